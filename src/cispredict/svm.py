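"""Balanced-bootstrap leave-one-out evaluation of a polynomial-kernel SVM.

The classifier is a soft-margin maximum-margin machine with kernel
K(x, y) = (x^T y + c)^d, d in 1..5, fitted by sequential minimal
optimisation (libsvm, via scikit-learn's bindings).  Evaluation follows the
small-cohort protocol used for CIS conversion prediction:

* class imbalance is removed by *balanced subsampling*: every member of the
  minority class is kept and an equally sized without-replacement sample is
  drawn from the majority class (22+22 = 44 at the 1-year horizon,
  31+31 = 62 at 3 years);
* each balanced cohort is scored by leave-one-out cross-validation (train
  on n-1, classify the held-out patient, rotate);
* the procedure is repeated over B bootstrap cohorts (default 100) and each
  metric is reported as mean, 95 % percentile CI and min-max range.

Features are standardised to zero mean / unit variance using the training
rows of each fold only (zero-variance columns keep scale 1), and a decision
value of exactly 0 is classified as non-converter.

The engine calls ``sklearn.svm._libsvm`` directly rather than through the
``SVC`` wrapper: the evaluation protocol refits the solver ~10^3 times per
bootstrap summary and the wrapper's per-fit validation overhead dominates
at these tiny training sizes.  A test cross-checks decision values against
``SVC`` on random problems.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import _libsvm as _lib

_lib.set_verbosity_wrap(0)

__all__ = [
    "SVMSpec",
    "PolySVM",
    "CVMetrics",
    "MetricSummary",
    "BootstrapSummary",
    "METRIC_NAMES",
    "balanced_subsample",
    "train_classifier",
    "loo_cv",
    "metrics_from_confusion",
    "bootstrap_evaluate",
]

METRIC_NAMES = ["accuracy", "sensitivity", "specificity", "ppv", "npv"]


@dataclass(frozen=True)
class SVMSpec:
    """Hyperparameters of the polynomial-kernel classifier.

    ``kernel_degree`` d in 1..5; ``kernel_offset`` is the additive constant
    c of the kernel; ``margin_penalty`` is the soft-margin cost C.  The
    solver iteration cap defaults to 10 million to allow convergence on
    hard problems.
    """

    kernel_degree: int = 1
    kernel_offset: float = 1.0
    margin_penalty: float = 1.0
    max_solver_iterations: int = 10_000_000
    standardize: bool = True

    def __post_init__(self) -> None:
        if not (isinstance(self.kernel_degree, (int, np.integer))
                and 1 <= self.kernel_degree <= 5):
            raise ValueError("kernel_degree must be an integer in [1, 5]")
        if self.margin_penalty <= 0:
            raise ValueError("margin_penalty must be positive")


class PolySVM:
    """Fitted polynomial-kernel classifier with per-fit standardisation.

    ``predict`` returns +1 (converter) / -1 (non-converter); a decision
    value of exactly 0 maps to -1.
    """

    def __init__(self, spec: SVMSpec):
        self.spec = spec
        self.converged: bool = True
        self.n_iter: int = 0
        self._model = None
        self._mean: np.ndarray | None = None
        self._scale: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PolySVM":
        X = np.ascontiguousarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        if self.spec.standardize:
            self._mean = X.mean(axis=0)
            scale = X.std(axis=0)
            scale[scale == 0.0] = 1.0  # zero-variance column: leave unscaled
            self._scale = scale
            X = (X - self._mean) / self._scale
        self._model = _lib.fit(
            X, y, svm_type=0, kernel="poly",
            degree=int(self.spec.kernel_degree), gamma=1.0,
            coef0=float(self.spec.kernel_offset),
            C=float(self.spec.margin_penalty), tol=1e-3,
            max_iter=int(self.spec.max_solver_iterations),
        )
        self.n_iter = int(np.asarray(self._model[8]).ravel()[0])
        fit_status = int(np.asarray(self._model[7]).ravel()[0]) if np.ndim(self._model[7]) else int(self._model[7])
        self.converged = (fit_status == 0
                          and self.n_iter < self.spec.max_solver_iterations)
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Signed distance to the separating surface; positive = converter."""
        if self._model is None:
            raise RuntimeError("classifier is not fitted")
        X = np.ascontiguousarray(np.atleast_2d(X), dtype=np.float64)
        if self.spec.standardize:
            X = (X - self._mean) / self._scale
        m = self._model
        raw = _lib.decision_function(
            X, m[0], m[1], m[2], m[3], m[4], m[5], m[6],
            svm_type=0, kernel="poly", degree=int(self.spec.kernel_degree),
            gamma=1.0, coef0=float(self.spec.kernel_offset),
        ).ravel()
        # libsvm's raw binary decision is oriented toward the smaller label;
        # negate so positive values mean the +1 (converter) class.
        return -raw

    def predict(self, X: np.ndarray) -> np.ndarray:
        dec = self.decision_function(X)
        return np.where(dec > 0.0, 1, -1)

    def training_error(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) != np.asarray(y)))


@dataclass
class CVMetrics:
    """Confusion counts and derived rates (percent) for one LOO-CV run.

    Undefined ratios (zero denominator) are NaN, never 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    n_unconverged: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "ppv": self.ppv, "npv": self.npv,
        }


def metrics_from_confusion(tp: int, fp: int, tn: int, fn: int) -> CVMetrics:
    """Derive the five rates (percent) from confusion counts.

    accuracy = 100 (tp+tn)/n; sensitivity = 100 tp/(tp+fn);
    specificity = 100 tn/(tn+fp); ppv = 100 tp/(tp+fp);
    npv = 100 tn/(tn+fn).  Ratios with a zero denominator are NaN.
    """
    counts = (tp, fp, tn, fn)
    if any(c < 0 for c in counts):
        raise ValueError("confusion counts must be nonnegative")
    total = sum(counts)
    if total == 0:
        raise ValueError("at least one count must be positive")

    def rate(num: int, den: int) -> float:
        return 100.0 * num / den if den > 0 else math.nan

    return CVMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=100.0 * (tp + tn) / total,
        sensitivity=rate(tp, tp + fn),
        specificity=rate(tn, tn + fp),
        ppv=rate(tp, tp + fp),
        npv=rate(tn, tn + fn),
    )


def balanced_subsample(cohort, seed) -> "CohortMatrix":
    """Balance the cohort by subsampling the majority class.

    All members of the minority class are retained; an equally sized
    uniform *without-replacement* sample is drawn from the majority class.
    The result has 2 x minority-size rows, in original row order.
    ``seed`` may be an integer or a ``numpy.random.Generator``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos = np.flatnonzero(cohort.y == 1)
    neg = np.flatnonzero(cohort.y == -1)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be non-empty")
    if len(pos) <= len(neg):
        minority, majority = pos, neg
    else:
        minority, majority = neg, pos
    pick = rng.choice(majority, size=len(minority), replace=False)
    rows = np.sort(np.concatenate([minority, pick]))
    return cohort.take(rows)


def train_classifier(train, subset: list[str], spec: SVMSpec) -> PolySVM:
    """Fit the polynomial-kernel classifier on a feature subset of a cohort."""
    if not subset:
        raise ValueError("feature subset must be non-empty")
    X = train.subset_matrix(subset)
    return PolySVM(spec).fit(X, train.y)


def loo_cv(cohort, subset: list[str], spec: SVMSpec) -> CVMetrics:
    """Leave-one-out cross-validation of the classifier on a cohort.

    Each patient in turn is held out, the classifier is trained on the
    remaining n-1, and the held-out patient is classified; confusion counts
    are aggregated over all n folds.  Folds whose solver fails to converge
    are counted in ``n_unconverged`` (their prediction is still used).
    """
    if cohort.n < 4:
        raise ValueError("LOO-CV needs at least 4 patients")
    if not subset:
        raise ValueError("feature subset must be non-empty")
    X = np.ascontiguousarray(cohort.subset_matrix(subset), dtype=np.float64)
    y = cohort.y
    if (y == 1).sum() == 0 or (y == -1).sum() == 0:
        raise ValueError("cohort must contain both classes")
    n = cohort.n
    tp = fp = tn = fn = 0
    n_unconverged = 0
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        y_train = y[mask]
        if (y_train == 1).sum() == 0 or (y_train == -1).sum() == 0:
            raise ValueError("a training fold lost an entire class")
        clf = PolySVM(spec).fit(X[mask], y_train)
        if not clf.converged:
            n_unconverged += 1
        pred = int(clf.predict(X[i])[0])
        truth = int(y[i])
        if truth == 1:
            tp += pred == 1
            fn += pred == -1
        else:
            tn += pred == -1
            fp += pred == 1
        mask[i] = True
    metrics = metrics_from_confusion(int(tp), int(fp), int(tn), int(fn))
    metrics.n_unconverged = n_unconverged
    return metrics


@dataclass
class MetricSummary:
    mean: float
    ci95_low: float
    ci95_high: float
    range_min: float
    range_max: float

    def as_dict(self) -> dict:
        return {"mean": self.mean, "ci95": [self.ci95_low, self.ci95_high],
                "range": [self.range_min, self.range_max]}


@dataclass
class BootstrapSummary:
    """Per-metric mean / 95 % percentile CI / range over B balanced bootstraps."""

    B: int
    seed: int
    metrics: dict[str, MetricSummary]
    values: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    n_unconverged: int = 0

    @property
    def mean_accuracy(self) -> float:
        return self.metrics["accuracy"].mean

    def as_dict(self) -> dict:
        out = {"B": self.B, "seed": self.seed, "n_unconverged": self.n_unconverged}
        out.update({name: ms.as_dict() for name, ms in self.metrics.items()})
        return out


def bootstrap_evaluate(cohort, subset: list[str], spec: SVMSpec,
                       B: int = 100, seed: int = 0) -> BootstrapSummary:
    """Evaluate a feature subset over B balanced-bootstrap LOO-CV runs.

    Bootstrap b uses a generator derived deterministically from the master
    seed (counter-based substreams), so identical seeds give identical
    summaries — and identical subsample draws across different feature
    subsets, enabling paired comparisons during feature selection.
    """
    if B < 2:
        raise ValueError("need B >= 2 bootstraps")
    per_metric: dict[str, list[float]] = {name: [] for name in METRIC_NAMES}
    n_unconverged = 0
    for b in range(B):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(b,)))
        sub = balanced_subsample(cohort, rng)
        m = loo_cv(sub, subset, spec)
        n_unconverged += m.n_unconverged
        for name in METRIC_NAMES:
            per_metric[name].append(getattr(m, name))
    metrics = {}
    values = {}
    for name, vals in per_metric.items():
        arr = np.asarray(vals, dtype=float)
        values[name] = arr
        finite = arr[np.isfinite(arr)]
        if len(finite) == 0:
            metrics[name] = MetricSummary(math.nan, math.nan, math.nan,
                                          math.nan, math.nan)
            continue
        lo, hi = np.percentile(finite, [2.5, 97.5])
        metrics[name] = MetricSummary(
            mean=float(finite.mean()), ci95_low=float(lo), ci95_high=float(hi),
            range_min=float(finite.min()), range_max=float(finite.max()))
    return BootstrapSummary(B=B, seed=seed, metrics=metrics, values=values,
                            n_unconverged=n_unconverged)
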