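"""Synthetic CIS cohort generator.

Real conversion-prediction cohorts (baseline PD/T2 scans, expert lesion
masks, clinical records, 1- and 3-year conversion labels) are not publicly
depositable, so every downstream stage of this package is exercised on
synthetic patients.  The generator emulates the structure such a cohort is
reported to have:

* lesion counts per patient follow an overdispersed (negative binomial)
  distribution calibrated so the proportions of patients with <=3 lesions,
  4-10 lesions and >10 lesions match the published cohort composition
  (14/74, 23/74, 37/74);
* lesion sizes follow a truncated geometric distribution whose three size
  bins (1-15, 16-36, 37+ voxels) are each well populated;
* class imbalance matches the study horizons: 22 converters / 52
  non-converters at 1 year, 31 / 39 at 3 years;
* converters can be given planted effects: higher lesion load, lesions
  closer to the vertical axis of the brain, younger age, more female and
  more spinal-cord presentations.

Lesions are grown as face-adjacent random-walk blobs (hence exactly
18-connected), placed around a periventricular ring inside an ellipsoidal
brain support, and appear hyperintense on both PD and T2.  The
template-space mask is produced by a fixed affine scale-and-shift of the
native lesion voxels; deformable registration is deliberately not emulated.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .design import CohortMatrix
from .grid import VoxelGrid3D, load_nifti, save_nifti

__all__ = [
    "CohortConfig",
    "PatientRecord",
    "CONVERTER",
    "NON_CONVERTER",
    "generate_cohort",
    "generate_null_cohort",
    "generate_feature_cohort",
    "generate_interaction_cohort",
    "sample_lesion_counts",
    "write_cohort",
    "read_cohort",
    "EFFECTS_1Y",
    "EFFECTS_3Y",
]

CONVERTER = 1
NON_CONVERTER = -1

# Baseline demographic parameters, anchored to the published cohort table:
# median age 33-34 (range 19-49), 25/74 male, presentation dominated by
# optic neuritis, EDSS median 1 (range 0-8).
_AGE_MEAN = 34.0
_AGE_SD = 7.5
_P_MALE = 25.0 / 74.0
_CIS_BASE_PROBS = np.array([0.86, 0.06, 0.07, 0.01])  # optic, spinal, brainstem, other
_EDSS_SD = 1.25
_MU_BACKGROUND = 100.0
_MU_AIR = 5.0

# Default planted converter effects (standardised mean shifts, converters
# minus non-converters): converters carry a higher lesion load, lesions
# closer to the vertical axis and the brain centre, younger age, fewer
# males, and more spinal-cord presentations.
EFFECTS_1Y: dict[str, float] = {
    "lesion_load": 1.0,
    "min_axis_dist": -0.8,
    "age": -0.5,
    "gender": -0.4,
    "cis_type": 0.8,
}
EFFECTS_3Y: dict[str, float] = {
    "lesion_load": 0.8,
    "lesion_count": 0.6,
    "min_axis_dist": -0.8,
    "mean_dist_center": -0.4,
    "age": -0.5,
    "edss": 0.3,
}


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic cohort.

    ``effect_sizes`` maps feature names (``age, gender, cis_type, edss,
    lesion_count, lesion_load, mean_pd, mean_t2, mean_dist_center,
    central_cube, min_axis_dist``) to standardised mean shifts of converters
    relative to non-converters.  Lattice defaults reproduce a 1.5 T axial
    dual-echo acquisition (256 x 256 x 46 at 0.9375 x 0.9375 x 3 mm) and a
    2 mm isotropic 91 x 109 x 91 template.
    """

    n_converters: int = 22
    n_nonconverters: int = 52
    horizon: str = "1y"
    effect_sizes: dict[str, float] = field(default_factory=dict)
    # lesion-count distribution: zero-truncated negative binomial
    lesion_count_r: float = 0.983
    lesion_count_mean: float = 13.98
    # lesion-size distribution: geometric on {1..size_max}
    lesion_size_p: float = 0.027
    lesion_size_max: int = 200
    noise_sd: float = 10.0
    contrast_pd: float = 30.0
    contrast_t2: float = 30.0
    native_shape: tuple[int, int, int] = (256, 256, 46)
    native_voxel_mm: tuple[float, float, float] = (0.9375, 0.9375, 3.0)
    template_shape: tuple[int, int, int] = (91, 109, 91)
    template_voxel_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_converters < 1 or self.n_nonconverters < 1:
            raise ValueError("both class counts must be >= 1")
        if self.horizon not in ("1y", "3y"):
            raise ValueError(f"horizon must be '1y' or '3y', got {self.horizon!r}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (0 < self.lesion_size_p < 1) or self.lesion_size_max < 1:
            raise ValueError("lesion size distribution cannot produce sizes >= 1 voxel")
        if self.lesion_count_r <= 0 or self.lesion_count_mean < 1:
            raise ValueError("lesion count distribution must support counts >= 1")

    @classmethod
    def preset_1y(cls, seed: int = 0, **overrides) -> "CohortConfig":
        """1-year study conditions: 22 converters vs 52 non-converters."""
        kw = dict(n_converters=22, n_nonconverters=52, horizon="1y",
                  effect_sizes=dict(EFFECTS_1Y), seed=seed)
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def preset_3y(cls, seed: int = 0, **overrides) -> "CohortConfig":
        """3-year study conditions: 31 converters vs 39 non-converters."""
        kw = dict(n_converters=31, n_nonconverters=39, horizon="3y",
                  effect_sizes=dict(EFFECTS_3Y), seed=seed)
        kw.update(overrides)
        return cls(**kw)


@dataclass
class PatientRecord:
    """One synthetic subject: masks, volumes, clinical fields and label."""

    id: str
    native_mask: VoxelGrid3D
    template_mask: VoxelGrid3D
    pd_volume: VoxelGrid3D
    t2_volume: VoxelGrid3D
    age: float
    gender_code: int  # 0 female, 1 male
    cis_type_code: int  # 1 optic neuritis, 2 spinal cord, 3 brainstem, 4 other
    edss: float
    label: int  # +1 converter, -1 non-converter
    horizon: str = "1y"

    def __post_init__(self) -> None:
        if not self.native_mask.values.any():
            raise ValueError("native mask must contain at least one lesion voxel")
        if not (self.native_mask.same_lattice(self.pd_volume)
                and self.native_mask.same_lattice(self.t2_volume)):
            raise ValueError("PD/T2 volumes must share the native mask lattice")
        if self.gender_code not in (0, 1):
            raise ValueError("gender_code must be 0 (female) or 1 (male)")
        if self.cis_type_code not in (1, 2, 3, 4):
            raise ValueError("cis_type_code must be in {1, 2, 3, 4}")
        if not (0.0 <= self.edss <= 10.0) or round(self.edss * 2) != self.edss * 2:
            raise ValueError("EDSS must lie in [0, 10] in steps of 0.5")
        if self.label not in (CONVERTER, NON_CONVERTER):
            raise ValueError("label must be +1 (converter) or -1 (non-converter)")


# --------------------------------------------------------------------------
# distribution moments (used to express planted effects in SD units)

@lru_cache(maxsize=32)
def _truncated_count_moments(r: float, mean: float) -> tuple[float, float]:
    """Mean and variance of the zero-truncated negative binomial."""
    p = r / (r + mean)
    k = np.arange(1, 2000)
    pmf = stats.nbinom.pmf(k, r, p)
    pmf = pmf / pmf.sum()
    m = float((k * pmf).sum())
    v = float(((k - m) ** 2 * pmf).sum())
    return m, v


@lru_cache(maxsize=32)
def _size_moments(p: float, cap: int) -> tuple[float, float]:
    """Mean and variance of the geometric distribution truncated at ``cap``."""
    k = np.arange(1, cap + 1, dtype=float)
    pmf = p * (1 - p) ** (k - 1)
    pmf = pmf / pmf.sum()
    m = float((k * pmf).sum())
    v = float(((k - m) ** 2 * pmf).sum())
    return m, v


def _load_moments(config: CohortConfig) -> tuple[float, float]:
    """Mean and SD of per-patient lesion load under the config's distributions."""
    en, vn = _truncated_count_moments(config.lesion_count_r, config.lesion_count_mean)
    es, vs = _size_moments(config.lesion_size_p, config.lesion_size_max)
    mean = en * es
    var = en * vs + vn * es ** 2
    return mean, float(np.sqrt(var))


# --------------------------------------------------------------------------
# geometry helpers

@lru_cache(maxsize=8)
def _brain_support(shape: tuple[int, int, int],
                   voxel: tuple[float, float, float]) -> np.ndarray:
    """Boolean ellipsoidal brain support centred on the central voxel."""
    vs = np.asarray(voxel)
    center = (np.asarray(shape) // 2) * vs
    semi = 0.45 * np.asarray(shape) * vs
    grids = np.ogrid[0:shape[0], 0:shape[1], 0:shape[2]]
    r2 = sum(((g * s - c) / a) ** 2 for g, s, c, a in zip(grids, vs, center, semi))
    return r2 <= 1.0


def _grow_blob(start: tuple[int, int, int], size: int,
               shape: tuple[int, int, int], rng: np.random.Generator,
               blocked: np.ndarray) -> np.ndarray:
    """Grow a face-connected blob of (up to) ``size`` voxels from ``start``.

    Face adjacency implies 18-connectivity of the result.  Voxels marked in
    ``blocked`` (other lesions plus their separating shell) are never
    entered, so distinct lesions keep distinct components; growth stops
    short only if the blob is trapped against the boundary or the shell.
    """
    blob = {start}
    cells = [start]
    max_attempts = 60 * size + 200
    attempts = 0
    while len(blob) < size and attempts < max_attempts:
        attempts += 1
        base = cells[int(rng.integers(len(cells)))]
        axis = int(rng.integers(3))
        step = 1 if rng.random() < 0.5 else -1
        nb = list(base)
        nb[axis] += step
        nbt = (nb[0], nb[1], nb[2])
        if (0 <= nbt[0] < shape[0] and 0 <= nbt[1] < shape[1]
                and 0 <= nbt[2] < shape[2] and nbt not in blob
                and not blocked[nbt]):
            blob.add(nbt)
            cells.append(nbt)
    return np.array(cells, dtype=int)


def _place_center(rng: np.random.Generator, config: CohortConfig,
                  radial_scale: float, force_central: bool) -> tuple[int, int, int]:
    """Draw one lesion placement centre (voxel index) in native space.

    Centres come from a periventricular in-plane ring (75 %) or a uniform
    background component inside the brain ellipsoid (25 %); the in-plane
    offset from the vertical axis is multiplied by ``radial_scale`` to plant
    distance effects.
    """
    shape = np.asarray(config.native_shape)
    vs = np.asarray(config.native_voxel_mm)
    center = (shape // 2) * vs
    semi = 0.45 * shape * vs
    if force_central:
        offset = rng.normal(0.0, 2.0, size=3)  # within a few mm of the centre
    elif rng.random() < 0.75:
        r_ring = 0.25 * min(semi[0], semi[1])
        phi = rng.uniform(0, 2 * np.pi)
        rho = abs(rng.normal(r_ring, 0.3 * r_ring))
        z = rng.normal(0.0, 0.25 * semi[2])
        offset = np.array([rho * np.cos(phi), rho * np.sin(phi), z])
    else:
        # uniform direction, cube-root radius: uniform in the ellipsoid
        direction = rng.normal(size=3)
        direction /= max(np.linalg.norm(direction), 1e-12)
        u = rng.random() ** (1.0 / 3.0)
        offset = direction * u * semi * 0.9
    offset[:2] *= radial_scale
    # keep inside the ellipsoid
    rad = np.sqrt(((offset / semi) ** 2).sum())
    if rad > 0.95:
        offset *= 0.95 / rad
    mm = center + offset
    idx = np.clip(np.rint(mm / vs).astype(int), 0, shape - 1)
    return (int(idx[0]), int(idx[1]), int(idx[2]))


def _map_to_template(native_idx: np.ndarray, config: CohortConfig) -> np.ndarray:
    """Fixed affine (per-axis scale about the lattice centres) native -> template."""
    n_shape = np.asarray(config.native_shape)
    t_shape = np.asarray(config.template_shape)
    n_vs = np.asarray(config.native_voxel_mm)
    t_vs = np.asarray(config.template_voxel_mm)
    scale = 0.9 * (t_shape * t_vs) / (n_shape * n_vs)
    n_center = (n_shape // 2) * n_vs
    t_center = (t_shape // 2) * t_vs
    mm = native_idx * n_vs
    t_mm = (mm - n_center) * scale + t_center
    t_idx = np.rint(t_mm / t_vs).astype(int)
    return np.clip(t_idx, 0, t_shape - 1)


# --------------------------------------------------------------------------
# per-patient sampling

def _sample_count(rng: np.random.Generator, config: CohortConfig, eff: float) -> int:
    r, mean = config.lesion_count_r, config.lesion_count_mean
    _, var = _truncated_count_moments(r, mean)
    m = max(1.0, mean + eff * np.sqrt(var))
    p = r / (r + m)
    for _ in range(1000):
        n = int(rng.negative_binomial(r, p))
        if n >= 1:
            return n
    return 1


@lru_cache(maxsize=64)
def _solve_size_p(target_mean: float, cap: int) -> float:
    """Geometric parameter whose cap-truncated mean equals ``target_mean``."""
    lo, hi = 1e-5, 0.95
    if _size_moments(lo, cap)[0] <= target_mean:
        return lo
    for _ in range(60):
        mid = np.sqrt(lo * hi)
        if _size_moments(mid, cap)[0] > target_mean:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def _sample_sizes(rng: np.random.Generator, config: CohortConfig,
                  n: int, eff_load: float) -> np.ndarray:
    es, _ = _size_moments(config.lesion_size_p, config.lesion_size_max)
    en, _ = _truncated_count_moments(config.lesion_count_r, config.lesion_count_mean)
    _, sd_load = _load_moments(config)
    target_mean = max(1.05, es + eff_load * sd_load / en)
    p = (config.lesion_size_p if eff_load == 0.0
         else _solve_size_p(target_mean, config.lesion_size_max))
    sizes = []
    for _ in range(n):
        s = int(rng.geometric(p))
        for _ in range(100):
            if s <= config.lesion_size_max:
                break
            s = int(rng.geometric(p))
        sizes.append(min(s, config.lesion_size_max))
    return np.asarray(sizes, dtype=int)


def _sample_clinical(rng: np.random.Generator, eff) -> tuple[float, int, int, float]:
    age = float(np.clip(rng.normal(_AGE_MEAN + eff("age") * _AGE_SD, _AGE_SD), 18.0, 60.0))
    p_male = float(np.clip(_P_MALE + eff("gender") * np.sqrt(_P_MALE * (1 - _P_MALE)),
                           0.02, 0.98))
    gender = int(rng.random() < p_male)
    probs = _CIS_BASE_PROBS.copy()
    # positive cis_type effect = more spinal-cord presentations (code 2)
    boost = np.clip(eff("cis_type") * 0.15, -probs[1] + 0.005, 0.6)
    probs[1] += boost
    probs[[0, 2, 3]] *= (1.0 - probs[1]) / probs[[0, 2, 3]].sum()
    cis = int(rng.choice([1, 2, 3, 4], p=probs / probs.sum()))
    edss_raw = rng.gamma(1.3, 1.0) + eff("edss") * _EDSS_SD
    edss = float(np.clip(np.round(edss_raw * 2) / 2, 0.0, 8.0))
    return age, gender, cis, edss


def _generate_patient(pid: str, converter: bool, index: int,
                      config: CohortConfig) -> PatientRecord:
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(index,)))

    def eff(name: str) -> float:
        return float(config.effect_sizes.get(name, 0.0)) if converter else 0.0

    age, gender, cis, edss = _sample_clinical(rng, eff)

    n_lesions = _sample_count(rng, config, eff("lesion_count"))
    sizes = _sample_sizes(rng, config, n_lesions, eff("lesion_load"))

    radial_scale = float(np.clip(
        1.0 + 0.3 * (eff("min_axis_dist") + eff("mean_dist_center")), 0.15, 3.0))
    p_central = float(np.clip(0.12 + 0.3 * eff("central_cube"), 0.0, 1.0))
    central_slot = int(rng.integers(n_lesions)) if rng.random() < p_central else -1

    shape = config.native_shape
    mask = np.zeros(shape, dtype=np.uint8)
    # lesions plus an 18-connected shell: keeps separate lesions from
    # merging into one component and from silently sharing voxels
    occupied = np.zeros(shape, dtype=bool)
    struct = ndimage.generate_binary_structure(3, 2)
    for j, size in enumerate(sizes):
        start = None
        for _ in range(50):
            cand = _place_center(rng, config, radial_scale,
                                 force_central=(j == central_slot))
            if not occupied[cand]:
                start = cand
                break
        if start is None:
            continue  # brain region saturated: drop this lesion
        cells = _grow_blob(start, int(size), shape, rng, occupied)
        mask[cells[:, 0], cells[:, 1], cells[:, 2]] = 1
        lo = np.maximum(cells.min(axis=0) - 2, 0)
        hi = np.minimum(cells.max(axis=0) + 3, shape)
        box = np.zeros(tuple(hi - lo), dtype=bool)
        box[tuple((cells - lo).T)] = True
        occupied[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= \
            ndimage.binary_dilation(box, structure=struct)
    if not mask.any():  # degenerate tiny lattice: guarantee one lesion voxel
        center = tuple(np.asarray(shape) // 2)
        mask[center] = 1
    lesion_idx = np.argwhere(mask)

    brain = _brain_support(config.native_shape, config.native_voxel_mm)
    noise = config.noise_sd

    def volume(contrast: float, eff_name: str) -> VoxelGrid3D:
        vals = rng.normal(_MU_AIR, 0.5 * noise, size=shape)
        vals[brain] = rng.normal(_MU_BACKGROUND, noise, size=int(brain.sum()))
        lesion_mu = _MU_BACKGROUND + contrast + eff(eff_name) * noise
        vals[mask.astype(bool)] = rng.normal(lesion_mu, noise, size=len(lesion_idx))
        np.clip(vals, 0.0, None, out=vals)
        return VoxelGrid3D(vals, config.native_voxel_mm)

    pd_vol = volume(config.contrast_pd, "mean_pd")
    t2_vol = volume(config.contrast_t2, "mean_t2")

    t_idx = _map_to_template(lesion_idx, config)
    template = np.zeros(config.template_shape, dtype=np.uint8)
    template[t_idx[:, 0], t_idx[:, 1], t_idx[:, 2]] = 1

    return PatientRecord(
        id=pid,
        native_mask=VoxelGrid3D(mask, config.native_voxel_mm),
        template_mask=VoxelGrid3D(template, config.template_voxel_mm),
        pd_volume=pd_vol,
        t2_volume=t2_vol,
        age=age,
        gender_code=gender,
        cis_type_code=cis,
        edss=edss,
        label=CONVERTER if converter else NON_CONVERTER,
        horizon=config.horizon,
    )


def generate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Generate a synthetic cohort of ``n_converters + n_nonconverters`` patients.

    Each patient is drawn from an independent, counter-derived substream of
    the master seed, so the cohort is bit-reproducible and independent of
    generation order.  Planted converter effects are applied as
    class-conditional shifts of the sampling distributions.
    """
    records = []
    n_total = config.n_converters + config.n_nonconverters
    for i in range(n_total):
        converter = i < config.n_converters
        pid = f"P{i + 1:03d}"
        records.append(_generate_patient(pid, converter, i, config))
    return records


def generate_null_cohort(n: int, seed: int,
                         config: CohortConfig | None = None) -> list[PatientRecord]:
    """Generate ``n`` patients whose labels are fair coin flips.

    All planted effects are removed, so the label carries no information
    about any feature — a calibration control for the classifier stack.
    ``n`` must be even (a balanced design is required downstream) and >= 4.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if n % 2 != 0:
        raise ValueError("n must be even (balanced design required downstream)")
    base = config if config is not None else CohortConfig()
    cfg = replace(base, n_converters=1, n_nonconverters=max(1, n - 1),
                  effect_sizes={}, seed=seed)
    label_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0xC01,)))
    labels = label_rng.integers(0, 2, size=n)
    if labels.min() == labels.max():  # degenerate draw: force both classes
        labels[0] = 1 - labels[0]
    records = []
    for i in range(n):
        rec = _generate_patient(f"P{i + 1:03d}", converter=False, index=i, config=cfg)
        rec.label = CONVERTER if labels[i] else NON_CONVERTER
        records.append(rec)
    return records


def sample_lesion_counts(config: CohortConfig, n: int, seed: int,
                         converter: bool = False) -> np.ndarray:
    """Draw ``n`` per-patient lesion counts from the config's count distribution.

    Exposed for calibration checks against the published lesion-count bins.
    """
    rng = np.random.default_rng(seed)
    eff = float(config.effect_sizes.get("lesion_count", 0.0)) if converter else 0.0
    return np.array([_sample_count(rng, config, eff) for _ in range(n)])


# --------------------------------------------------------------------------
# feature-level cohorts (for classifier and selection simulations)

def generate_feature_cohort(n_converters: int, n_nonconverters: int,
                            n_features: int = 6,
                            effect_sizes: dict[str, float] | None = None,
                            seed: int = 0,
                            feature_names: list[str] | None = None,
                            horizon: str = "1y") -> CohortMatrix:
    """Draw a Gaussian design matrix with planted class-mean shifts.

    Every feature is N(0, 1) in non-converters; converters are shifted by
    the requested effect size (in SD units).  This is the natural carrier
    for 'one informative feature, the rest pure noise' simulations, where
    the image-level generator cannot isolate single features.
    """
    if n_converters < 1 or n_nonconverters < 1:
        raise ValueError("both class counts must be >= 1")
    names = feature_names if feature_names is not None else [f"f{j}" for j in range(n_features)]
    if len(names) != n_features:
        raise ValueError("feature_names length must equal n_features")
    rng = np.random.default_rng(seed)
    n = n_converters + n_nonconverters
    X = rng.normal(size=(n, n_features))
    y = np.r_[np.full(n_converters, CONVERTER), np.full(n_nonconverters, NON_CONVERTER)]
    if effect_sizes:
        for name, eff in effect_sizes.items():
            j = names.index(name)
            X[:n_converters, j] += float(eff)
    ids = [f"S{i + 1:03d}" for i in range(n)]
    return CohortMatrix(ids=ids, X=X, y=y.astype(int), horizon=horizon,
                        columns=list(names),
                        feature_map={name: [name] for name in names})


def generate_interaction_cohort(n_per_class: int, n_noise: int = 4,
                                seed: int = 0,
                                decoy_effect: float = 0.0) -> CohortMatrix:
    """Two features informative only jointly (XOR-style), plus pure noise.

    Converters have sign-agreeing (x1, x2); non-converters sign-opposed.
    Neither feature separates the classes marginally, but their product
    does, so a degree-2 polynomial kernel on the pair succeeds where any
    single feature fails.  A nonzero ``decoy_effect`` adds a feature with a
    moderate marginal mean shift: a greedy forward search then picks the
    decoy first and tends to stall on it, while an exhaustive search still
    finds the jointly optimal pair — the canonical greedy-suboptimal case.
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    mag = lambda size: rng.uniform(0.5, 1.5, size=size)
    signs_conv = np.where(rng.random(n_per_class) < 0.5, 1.0, -1.0)
    x1_conv = signs_conv * mag(n_per_class)
    x2_conv = signs_conv * mag(n_per_class)
    signs_non = np.where(rng.random(n_per_class) < 0.5, 1.0, -1.0)
    x1_non = signs_non * mag(n_per_class)
    x2_non = -signs_non * mag(n_per_class)
    n_extra = n_noise + (1 if decoy_effect else 0)
    X = np.empty((n, 2 + n_extra))
    X[:n_per_class, 0] = x1_conv
    X[:n_per_class, 1] = x2_conv
    X[n_per_class:, 0] = x1_non
    X[n_per_class:, 1] = x2_non
    X[:, 2:] = rng.normal(size=(n, n_extra))
    names = ["x1", "x2"]
    if decoy_effect:
        X[:n_per_class, 2] += float(decoy_effect)
        names.append("decoy")
    names += [f"noise{j}" for j in range(n_noise)]
    y = np.r_[np.full(n_per_class, CONVERTER), np.full(n_per_class, NON_CONVERTER)]
    ids = [f"S{i + 1:03d}" for i in range(n)]
    return CohortMatrix(ids=ids, X=X, y=y.astype(int), horizon="1y",
                        columns=names, feature_map={m: [m] for m in names})


# --------------------------------------------------------------------------
# cohort I/O

CLINICAL_CSV_COLUMNS = ["id", "age", "gender", "cis_type", "edss", "label_1y", "label_3y"]


def write_cohort(records: list[PatientRecord], outdir: str | os.PathLike) -> None:
    """Write per-patient NIfTI volumes and one clinical CSV.

    Files: ``<id>_pd.nii.gz``, ``<id>_t2.nii.gz``, ``<id>_mask_native.nii.gz``,
    ``<id>_mask_template.nii.gz`` and ``clinical.csv`` with columns
    ``id,age,gender,cis_type,edss,label_1y,label_3y`` (labels coded
    1 = converter, 0 = non-converter; the column for the horizon not
    generated is left blank).
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    rows = []
    for rec in records:
        save_nifti(rec.pd_volume, os.path.join(outdir, f"{rec.id}_pd.nii.gz"))
        save_nifti(rec.t2_volume, os.path.join(outdir, f"{rec.id}_t2.nii.gz"))
        save_nifti(rec.native_mask, os.path.join(outdir, f"{rec.id}_mask_native.nii.gz"))
        save_nifti(rec.template_mask, os.path.join(outdir, f"{rec.id}_mask_template.nii.gz"))
        lab = 1 if rec.label == CONVERTER else 0
        rows.append({
            "id": rec.id, "age": rec.age, "gender": rec.gender_code,
            "cis_type": rec.cis_type_code, "edss": rec.edss,
            "label_1y": lab if rec.horizon == "1y" else "",
            "label_3y": lab if rec.horizon == "3y" else "",
        })
    pd.DataFrame(rows, columns=CLINICAL_CSV_COLUMNS).to_csv(
        os.path.join(outdir, "clinical.csv"), index=False)


def read_cohort(indir: str | os.PathLike) -> list[PatientRecord]:
    """Read a cohort written by :func:`write_cohort`."""
    indir = os.fspath(indir)
    table = pd.read_csv(os.path.join(indir, "clinical.csv"))
    records = []
    for _, row in table.iterrows():
        pid = str(row["id"])
        if not pd.isna(row.get("label_1y")) and str(row.get("label_1y")) != "":
            horizon, lab = "1y", int(row["label_1y"])
        else:
            horizon, lab = "3y", int(row["label_3y"])
        native = load_nifti(os.path.join(indir, f"{pid}_mask_native.nii.gz"))
        native = VoxelGrid3D(np.rint(native.values).astype(np.uint8), native.voxel_size_mm)
        template = load_nifti(os.path.join(indir, f"{pid}_mask_template.nii.gz"))
        template = VoxelGrid3D(np.rint(template.values).astype(np.uint8), template.voxel_size_mm)
        records.append(PatientRecord(
            id=pid,
            native_mask=native,
            template_mask=template,
            pd_volume=load_nifti(os.path.join(indir, f"{pid}_pd.nii.gz")),
            t2_volume=load_nifti(os.path.join(indir, f"{pid}_t2.nii.gz")),
            age=float(row["age"]),
            gender_code=int(row["gender"]),
            cis_type_code=int(row["cis_type"]),
            edss=float(row["edss"]),
            label=CONVERTER if lab == 1 else NON_CONVERTER,
            horizon=horizon,
        ))
    return records
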