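"""Wrapper feature selection: greedy forward search and exhaustive search.

Both strategies score a candidate feature subset by its mean balanced-
bootstrap LOO-CV accuracy, evaluated at every allowed polynomial degree
(1..5 by default) and represented by its best degree.  The same bootstrap
seed stream is reused for every candidate, so subset comparisons are
paired: resampling noise cancels out of the selection decision.

* Forward selection ("fRFE" in the source study's terminology) starts from
  the best single feature and adds, at each step, the remaining feature
  that maximises accuracy, stopping as soon as the best extension no longer
  improves on the incumbent (non-strict stop: a plateau stops the search).
  Greedy search has an inherent control for redundant features — a
  duplicated column is never needed — but can miss interactions.
* Exhaustive search enumerates all 2^k subsets (the empty set is counted
  but not evaluated; 4096 models for the full 12 features) and returns the
  argmax with deterministic tie-breaking.  With thousands of models scored
  on one small cohort this is a multiple-comparisons exercise, and a
  warning says so; no statistical correction is applied.

Ties anywhere are broken toward the lower degree, then the smaller subset,
then lexicographic position in the canonical feature order: the least
complex of the equally accurate candidates wins.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .svm import BootstrapSummary, SVMSpec, bootstrap_evaluate

__all__ = [
    "SelectionStep",
    "SelectionResult",
    "StrategyComparison",
    "forward_select",
    "exhaustive_search",
    "compare_strategies",
]

DEFAULT_DEGREES = (1, 2, 3, 4, 5)

#: Guard for exhaustive enumeration (2^20 subsets is already absurd).
MAX_EXHAUSTIVE_FEATURES = 20


@dataclass
class SelectionStep:
    """One evaluated candidate during a search."""

    step: int
    candidate: str | None
    subset: list[str]
    degree: int
    mean_accuracy: float
    chosen: bool = False


@dataclass
class SelectionResult:
    trace: list[SelectionStep]
    best_subset: list[str]
    best_degree: int
    best_summary: BootstrapSummary
    strategy: str
    n_enumerated: int | None = None

    @property
    def best_accuracy(self) -> float:
        return self.best_summary.mean_accuracy

    def as_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "best_subset": list(self.best_subset),
            "best_degree": self.best_degree,
            "best_accuracy": self.best_accuracy,
            "n_enumerated": self.n_enumerated,
            "summary": self.best_summary.as_dict(),
            "trace": [
                {"step": s.step, "candidate": s.candidate, "subset": list(s.subset),
                 "degree": s.degree, "mean_accuracy": s.mean_accuracy,
                 "chosen": s.chosen}
                for s in self.trace
            ],
        }


def _canonical(subset, order: list[str]) -> list[str]:
    return [f for f in order if f in subset]


def _evaluate_subset(cohort, subset: list[str], degrees, base_spec: SVMSpec,
                     B: int, seed: int) -> tuple[int, BootstrapSummary]:
    """Score one subset at every degree; return (best degree, its summary)."""
    best = None
    for d in degrees:
        spec = replace(base_spec, kernel_degree=int(d))
        summary = bootstrap_evaluate(cohort, subset, spec, B=B, seed=seed)
        key = (-summary.mean_accuracy, d)
        if best is None or key < best[0]:
            best = (key, int(d), summary)
    return best[1], best[2]


def _better(acc_a: float, key_a: tuple, acc_b: float, key_b: tuple) -> bool:
    """True if candidate a beats candidate b (higher accuracy, then simpler)."""
    return (-acc_a, *key_a) < (-acc_b, *key_b)


def forward_select(cohort, features: list[str] | None = None,
                   degrees=DEFAULT_DEGREES, B: int = 100, seed: int = 0,
                   base_spec: SVMSpec = SVMSpec()) -> SelectionResult:
    """Greedy forward wrapper selection by mean bootstrap LOO accuracy.

    Step 0 scores every feature alone (each at its best degree); each later
    step scores every extension of the incumbent set by one remaining
    feature.  The search stops when the best extension's accuracy is <= the
    incumbent's ("does not increase anymore").
    """
    order = list(features) if features is not None else list(cohort.feature_names)
    if len(order) < 2:
        raise ValueError("need at least 2 candidate features")
    pos = {f: i for i, f in enumerate(order)}

    trace: list[SelectionStep] = []
    incumbent: list[str] = []
    incumbent_acc = -np.inf
    incumbent_degree = 0
    incumbent_summary: BootstrapSummary | None = None

    step = 0
    remaining = list(order)
    while remaining:
        best_cand = None  # (acc, tiekey, feature, subset, degree, summary)
        for f in remaining:
            subset = _canonical(incumbent + [f], order)
            degree, summary = _evaluate_subset(cohort, subset, degrees,
                                               base_spec, B, seed)
            acc = summary.mean_accuracy
            trace.append(SelectionStep(step=step, candidate=f, subset=subset,
                                       degree=degree, mean_accuracy=acc))
            tiekey = (degree, len(subset), tuple(pos[x] for x in subset))
            if best_cand is None or _better(acc, tiekey, best_cand[0], best_cand[1]):
                best_cand = (acc, tiekey, f, subset, degree, summary)
        acc, _, f, subset, degree, summary = best_cand
        if acc <= incumbent_acc:
            break  # no improvement: stop before accepting
        for s in trace:
            if s.step == step and s.candidate == f:
                s.chosen = True
        incumbent, incumbent_acc = subset, acc
        incumbent_degree, incumbent_summary = degree, summary
        remaining = [x for x in remaining if x != f]
        step += 1

    return SelectionResult(trace=trace, best_subset=incumbent,
                           best_degree=incumbent_degree,
                           best_summary=incumbent_summary, strategy="forward")


def exhaustive_search(cohort, features: list[str] | None = None,
                      degrees=DEFAULT_DEGREES, B: int = 100, seed: int = 0,
                      base_spec: SVMSpec = SVMSpec()) -> SelectionResult:
    """Score every non-empty subset of the features; return the argmax.

    All 2^k subsets are enumerated (the empty subset is counted but skipped
    for evaluation).  Subsets are visited by increasing size, then
    lexicographically in canonical feature order, which together with the
    tie-break rules makes the result deterministic.
    """
    order = list(features) if features is not None else list(cohort.feature_names)
    k = len(order)
    if k > MAX_EXHAUSTIVE_FEATURES:
        raise ValueError(f"exhaustive search limited to {MAX_EXHAUSTIVE_FEATURES} features")
    n_enumerated = 2 ** k
    warnings.warn(
        f"exhaustive search scores {n_enumerated - 1} models on one cohort; "
        "the winner is subject to a multiple-comparisons (winner's curse) bias "
        "and its accuracy is likely optimistic on unseen data.",
        UserWarning, stacklevel=2)
    pos = {f: i for i, f in enumerate(order)}

    trace: list[SelectionStep] = []
    best = None  # (acc, tiekey, subset, degree, summary)
    for size in range(1, k + 1):
        for combo in itertools.combinations(order, size):
            subset = list(combo)
            degree, summary = _evaluate_subset(cohort, subset, degrees,
                                               base_spec, B, seed)
            acc = summary.mean_accuracy
            trace.append(SelectionStep(step=size, candidate=None, subset=subset,
                                       degree=degree, mean_accuracy=acc))
            tiekey = (degree, len(subset), tuple(pos[x] for x in subset))
            if best is None or _better(acc, tiekey, best[0], best[1]):
                best = (acc, tiekey, subset, degree, summary)
    acc, _, subset, degree, summary = best
    for s in trace:
        if s.subset == subset and s.degree == degree:
            s.chosen = True
            break
    return SelectionResult(trace=trace, best_subset=subset, best_degree=degree,
                           best_summary=summary, strategy="exhaustive",
                           n_enumerated=n_enumerated)


@dataclass
class StrategyComparison:
    """Side-by-side result of forward vs exhaustive search on one cohort."""

    forward: SelectionResult
    exhaustive: SelectionResult
    accuracy_gap: float  # exhaustive minus forward, >= 0 on shared seeds
    same_subset: bool
    forward_chance_level: bool
    exhaustive_chance_level: bool

    def as_dict(self) -> dict:
        return {
            "forward": self.forward.as_dict(),
            "exhaustive": self.exhaustive.as_dict(),
            "accuracy_gap": self.accuracy_gap,
            "same_subset": self.same_subset,
            "forward_chance_level": self.forward_chance_level,
            "exhaustive_chance_level": self.exhaustive_chance_level,
        }


def compare_strategies(cohort, features: list[str] | None = None,
                       degrees=DEFAULT_DEGREES, B: int = 100, seed: int = 0,
                       base_spec: SVMSpec = SVMSpec()) -> StrategyComparison:
    """Run both searches on identical bootstrap seeds and compare.

    A strategy is flagged as chance-level when the 95 % bootstrap CI of its
    winning accuracy reaches down to 50 % — the hallmark of a cohort whose
    labels carry no signal.
    """
    fwd = forward_select(cohort, features, degrees, B, seed, base_spec)
    exh = exhaustive_search(cohort, features, degrees, B, seed, base_spec)

    def chance(res: SelectionResult) -> bool:
        return res.best_summary.metrics["accuracy"].ci95_low <= 50.0

    return StrategyComparison(
        forward=fwd, exhaustive=exh,
        accuracy_gap=exh.best_accuracy - fwd.best_accuracy,
        same_subset=sorted(fwd.best_subset) == sorted(exh.best_subset),
        forward_chance_level=chance(fwd),
        exhaustive_chance_level=chance(exh),
    )
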