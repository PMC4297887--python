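"""Design-matrix assembly: clinical coding and feature/label alignment.

Twelve named features span fourteen numeric dimensions: the lesion size
profile is one selectable feature occupying three columns (counts of small,
medium and large lesions).  Clinical coding follows the study conventions:
gender 1 = male / 0 = female; CIS presentation 1 = optic neuritis,
2 = spinal cord, 3 = brainstem, 4 = other.  Labels are +1 converter /
-1 non-converter for a chosen follow-up horizon.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FEATURE_NAMES",
    "COLUMN_NAMES",
    "FEATURE_COLUMNS",
    "CohortMatrix",
    "encode_clinical",
    "assemble",
    "build_design_matrix",
]

#: The 12 selectable features, in canonical order.
FEATURE_NAMES = [
    "age",
    "gender",
    "cis_type",
    "edss",
    "lesion_count",
    "lesion_load",
    "mean_pd",
    "mean_t2",
    "mean_dist_center",
    "central_cube",
    "min_axis_dist",
    "size_profile",
]

#: The 14 numeric columns, in canonical order.
COLUMN_NAMES = [
    "age",
    "gender",
    "cis_type",
    "edss",
    "lesion_count",
    "lesion_load",
    "mean_pd",
    "mean_t2",
    "mean_dist_center",
    "central_cube",
    "min_axis_dist",
    "n_small",
    "n_medium",
    "n_large",
]

#: Feature name -> the columns it selects (size_profile spans three).
FEATURE_COLUMNS: dict[str, list[str]] = {
    name: [name] for name in FEATURE_NAMES if name != "size_profile"
}
FEATURE_COLUMNS["size_profile"] = ["n_small", "n_medium", "n_large"]


@dataclass
class CohortMatrix:
    """A cohort's design matrix with ids, labels and feature->column map."""

    ids: list[str]
    X: np.ndarray  # n_patients x n_columns
    y: np.ndarray  # +1 converter / -1 non-converter
    horizon: str = "1y"
    columns: list[str] = field(default_factory=lambda: list(COLUMN_NAMES))
    feature_map: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in FEATURE_COLUMNS.items()})

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.ids):
            raise ValueError("X must be n_patients x n_columns")
        if self.X.shape[1] != len(self.columns):
            raise ValueError("X width must match the column list")
        if len(self.y) != len(self.ids):
            raise ValueError("labels must align with ids")
        if not np.isin(self.y, (-1, 1)).all():
            raise ValueError("labels must be +1 or -1")
        if np.isnan(self.X).any():
            raise ValueError("design matrix must not contain missing values")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def feature_names(self) -> list[str]:
        return list(self.feature_map.keys())

    def column_indices(self, feature_subset: list[str]) -> list[int]:
        """Columns selected by a list of feature names (canonical order)."""
        cols: list[int] = []
        lookup = {c: i for i, c in enumerate(self.columns)}
        for name in self.feature_names:  # canonical order, not request order
            if name in feature_subset:
                cols.extend(lookup[c] for c in self.feature_map[name])
        unknown = set(feature_subset) - set(self.feature_names)
        if unknown:
            raise KeyError(f"unknown features: {sorted(unknown)}")
        return cols

    def subset_matrix(self, feature_subset: list[str]) -> np.ndarray:
        return self.X[:, self.column_indices(feature_subset)]

    def take(self, rows: np.ndarray) -> "CohortMatrix":
        return CohortMatrix(ids=[self.ids[i] for i in rows], X=self.X[rows],
                            y=self.y[rows], horizon=self.horizon,
                            columns=list(self.columns),
                            feature_map={k: list(v) for k, v in self.feature_map.items()})

    def to_csv(self, path: str | os.PathLike) -> None:
        frame = pd.DataFrame(self.X, columns=self.columns)
        frame.insert(0, "id", self.ids)
        frame["label"] = self.y
        frame.to_csv(os.fspath(path), index=False)

    @classmethod
    def from_csv(cls, path: str | os.PathLike, horizon: str = "1y") -> "CohortMatrix":
        frame = pd.read_csv(os.fspath(path), float_precision="round_trip")
        ids = [str(v) for v in frame["id"]]
        y = frame["label"].to_numpy(dtype=int)
        columns = [c for c in frame.columns if c not in ("id", "label")]
        X = frame[columns].to_numpy(dtype=float)
        if columns == COLUMN_NAMES:
            fmap = {k: list(v) for k, v in FEATURE_COLUMNS.items()}
        else:
            fmap = {c: [c] for c in columns}
        return cls(ids=ids, X=X, y=y, horizon=horizon, columns=columns, feature_map=fmap)


def encode_clinical(record) -> np.ndarray:
    """Encode one record's clinical fields as (age, gender, cis_type, edss).

    Gender is 1 male / 0 female; CIS presentation is coded 1 = optic
    neuritis, 2 = spinal cord, 3 = brainstem, 4 = other; EDSS enters raw.
    """
    if record.gender_code not in (0, 1):
        raise ValueError(f"unknown gender code {record.gender_code}")
    if record.cis_type_code not in (1, 2, 3, 4):
        raise ValueError(f"unknown CIS category {record.cis_type_code}")
    return np.array([float(record.age), float(record.gender_code),
                     float(record.cis_type_code), float(record.edss)])


def assemble(ids: list[str], feature_sets, clinical, labels, horizon: str) -> CohortMatrix:
    """Merge lesion features, clinical vectors and labels into a CohortMatrix.

    ``feature_sets`` are :class:`~cispredict.features.LesionFeatureSet`
    objects and ``clinical`` the 4-vectors from :func:`encode_clinical`,
    aligned with ``ids`` and ``labels``.  Rows are sorted by id, so the
    result is independent of input order.
    """
    if not (len(ids) == len(feature_sets) == len(clinical) == len(labels)):
        raise ValueError("ids, features, clinical and labels must align")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient ids")
    for lab in labels:
        if lab not in (-1, 1):
            raise ValueError(f"missing or invalid label for horizon {horizon}: {lab!r}")
    order = np.argsort(np.asarray(ids, dtype=object))
    rows = []
    for i in order:
        fs, cl = feature_sets[i], clinical[i]
        rows.append(np.concatenate([
            np.asarray(cl, dtype=float),
            [fs.lesion_count, fs.lesion_load_voxels,
             fs.mean_pd_intensity, fs.mean_t2_intensity,
             fs.mean_dist_to_center_mm, fs.central_cube_presence,
             fs.min_centroid_axis_dist_mm,
             fs.size_profile[0], fs.size_profile[1], fs.size_profile[2]],
        ]))
    return CohortMatrix(ids=[ids[i] for i in order], X=np.vstack(rows),
                        y=np.asarray(labels)[order], horizon=horizon)


def build_design_matrix(records, horizon: str | None = None) -> CohortMatrix:
    """Extract features and assemble the design matrix for a record list."""
    from .features import extract_all  # local import to keep modules acyclic

    horizon = horizon or records[0].horizon
    ids = [rec.id for rec in records]
    feats = [extract_all(rec) for rec in records]
    clin = [encode_clinical(rec) for rec in records]
    labels = [rec.label for rec in records]
    return assemble(ids, feats, clin, labels, horizon)
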