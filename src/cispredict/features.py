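"""Lesion-mask feature extraction.

Eight features are computed per patient from the binary lesion masks and
the paired PD/T2 intensity volumes:

1. lesion count           (native mask, 18-connected components)
2. lesion load            (native mask, voxels)
3. mean PD intensity      (native mask over PD volume)
4. mean T2 intensity      (native mask over T2 volume)
5. mean distance of lesional voxels to the brain centre (template mask, mm)
6. presence of lesions inside a 1 cm^3 cube at the brain centre (template)
7. shortest distance of a lesion centroid to the vertical axis (template, mm)
8. lesion size profile    (native mask: small 1-15 / medium 16-36 / large 37+)

Conventions (fixed for determinism and documented in the methods note):

* "Brain centre" is the central voxel of the template lattice,
  index (nx//2, ny//2, nz//2); all distances use voxel sizes in mm.
* The vertical axis is the inferior-superior line (axis 2) through the
  central voxel; feature 7 is the in-plane (axis 0 x axis 1) Euclidean
  distance of the component centroid to that line.
* The central cube is the closed box |delta| <= side/2 per axis on voxel
  centres, side 10 mm by default.
* Components are 18-connected (faces + edges, corners excluded) and
  labelled in first-seen raster order.
* Empty masks are a hard error: inclusion requires at least one lesion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import VoxelGrid3D

__all__ = [
    "LabeledComponents",
    "LesionFeatureSet",
    "connected_components",
    "lesion_count",
    "lesion_load",
    "mean_lesion_intensity",
    "mean_distance_to_center",
    "central_cube_presence",
    "min_centroid_axis_distance",
    "size_profile",
    "extract_all",
    "extract_cohort",
    "SIZE_BIN_SMALL_MAX",
    "SIZE_BIN_MEDIUM_MAX",
]

# Size-profile bin edges, in voxels: small 1-15, medium 16-36, large 37+.
SIZE_BIN_SMALL_MAX = 15
SIZE_BIN_MEDIUM_MAX = 36

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class LabeledComponents:
    """Connected-component labelling of a binary mask.

    ``label_grid`` holds integer labels 1..n_components (0 = background),
    assigned in first-seen raster order; ``component_sizes[i]`` is the voxel
    count of component ``i + 1``.
    """

    label_grid: VoxelGrid3D
    n_components: int
    component_sizes: np.ndarray


@dataclass
class LesionFeatureSet:
    """The eight lesion-derived features for one patient."""

    lesion_count: int
    lesion_load_voxels: int
    mean_pd_intensity: float
    mean_t2_intensity: float
    mean_dist_to_center_mm: float
    central_cube_presence: int
    min_centroid_axis_dist_mm: float
    size_profile: tuple[int, int, int]


def _check_binary_nonempty(mask: VoxelGrid3D, require_nonempty: bool = True) -> np.ndarray:
    if not mask.is_binary:
        raise ValueError("mask must be binary (values in {0, 1})")
    arr = mask.values.astype(bool)
    if require_nonempty and not arr.any():
        raise ValueError("mask is empty: at least one lesion voxel is required")
    return arr


def connected_components(mask: VoxelGrid3D, connectivity: int = 18) -> LabeledComponents:
    """Label connected components of a binary mask.

    ``connectivity`` is the number of neighbouring voxels considered
    adjacent: 6 (faces), 18 (faces + edges, the default used throughout),
    or 26 (faces + edges + corners).  Labels are renumbered so that
    component k is the k-th component encountered in raster (C) order.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of 6, 18, 26; got {connectivity}")
    arr = _check_binary_nonempty(mask, require_nonempty=False)
    labels, n = ndimage.label(arr, structure=_STRUCTURES[connectivity])
    if n > 0:
        flat = labels.ravel(order="C")
        uniq, first = np.unique(flat, return_index=True)
        keep = uniq > 0
        order = np.argsort(first[keep])  # labels sorted by first raster appearance
        remap = np.zeros(n + 1, dtype=labels.dtype)
        remap[uniq[keep][order]] = np.arange(1, n + 1)
        labels = remap[labels]
    sizes = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    return LabeledComponents(
        label_grid=VoxelGrid3D(labels, mask.voxel_size_mm),
        n_components=int(n),
        component_sizes=sizes,
    )


def lesion_count(mask: VoxelGrid3D) -> int:
    """Number of 18-connected lesions in the (native) mask."""
    _check_binary_nonempty(mask)
    return connected_components(mask, 18).n_components


def lesion_load(mask: VoxelGrid3D) -> int:
    """Total lesion volume in voxels."""
    arr = _check_binary_nonempty(mask)
    return int(arr.sum())


def mean_lesion_intensity(mask: VoxelGrid3D, volume: VoxelGrid3D) -> float:
    """Arithmetic mean of ``volume`` over the mask-positive voxels."""
    arr = _check_binary_nonempty(mask)
    if not mask.same_lattice(volume):
        raise ValueError("mask and intensity volume must share the same lattice")
    return float(volume.values[arr].mean())


def _lesion_coords_mm(mask_arr: np.ndarray, voxel_size: tuple[float, float, float]) -> np.ndarray:
    idx = np.argwhere(mask_arr)
    return idx * np.asarray(voxel_size)


def mean_distance_to_center(template_mask: VoxelGrid3D) -> float:
    """Mean Euclidean distance (mm) of lesional voxels to the template centre voxel."""
    arr = _check_binary_nonempty(template_mask)
    coords = _lesion_coords_mm(arr, template_mask.voxel_size_mm)
    center = template_mask.center_mm()
    return float(np.linalg.norm(coords - center, axis=1).mean())


def central_cube_presence(template_mask: VoxelGrid3D, side_mm: float = 10.0) -> int:
    """1 if any lesional voxel centre lies in the closed cube of edge ``side_mm``
    centred on the template centre voxel, else 0."""
    if side_mm <= 0:
        raise ValueError("side_mm must be positive")
    arr = _check_binary_nonempty(template_mask)
    coords = _lesion_coords_mm(arr, template_mask.voxel_size_mm)
    delta = np.abs(coords - template_mask.center_mm())
    inside = (delta <= side_mm / 2.0).all(axis=1)
    return int(inside.any())


def min_centroid_axis_distance(template_mask: VoxelGrid3D) -> float:
    """Shortest in-plane distance (mm) of any lesion centroid to the vertical axis.

    Centroids are unweighted means of voxel-centre coordinates of each
    18-connected component; the vertical axis is the inferior-superior line
    through the central voxel (intersection of the midsagittal and
    midcoronal planes).
    """
    _check_binary_nonempty(template_mask)
    comp = connected_components(template_mask, 18)
    labels = comp.label_grid.values
    vs = np.asarray(template_mask.voxel_size_mm)
    center = template_mask.center_mm()
    best = np.inf
    for k in range(1, comp.n_components + 1):
        idx = np.argwhere(labels == k)
        centroid = idx.mean(axis=0) * vs
        d = float(np.hypot(centroid[0] - center[0], centroid[1] - center[1]))
        best = min(best, d)
    return best


def size_profile(mask: VoxelGrid3D) -> tuple[int, int, int]:
    """Counts of 18-connected components that are small (1-15 voxels),
    medium (16-36) and large (37+)."""
    _check_binary_nonempty(mask)
    sizes = connected_components(mask, 18).component_sizes
    n_small = int((sizes <= SIZE_BIN_SMALL_MAX).sum())
    n_medium = int(((sizes > SIZE_BIN_SMALL_MAX) & (sizes <= SIZE_BIN_MEDIUM_MAX)).sum())
    n_large = int((sizes > SIZE_BIN_MEDIUM_MAX).sum())
    return (n_small, n_medium, n_large)


def extract_all(record) -> LesionFeatureSet:
    """Compute all eight lesion features for one patient record.

    Count, load, intensities and size profile are native-space quantities;
    the three distance/location features are computed on the template-space
    mask.
    """
    native = record.native_mask
    return LesionFeatureSet(
        lesion_count=lesion_count(native),
        lesion_load_voxels=lesion_load(native),
        mean_pd_intensity=mean_lesion_intensity(native, record.pd_volume),
        mean_t2_intensity=mean_lesion_intensity(native, record.t2_volume),
        mean_dist_to_center_mm=mean_distance_to_center(record.template_mask),
        central_cube_presence=central_cube_presence(record.template_mask),
        min_centroid_axis_dist_mm=min_centroid_axis_distance(record.template_mask),
        size_profile=size_profile(native),
    )


FEATURE_CSV_COLUMNS = [
    "id",
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


def extract_cohort(records) -> pd.DataFrame:
    """Extract features for a list of patient records into a table.

    Returns a DataFrame with one row per patient, columns
    ``id,lesion_count,lesion_load,mean_pd,mean_t2,mean_dist_center,
    central_cube,min_axis_dist,n_small,n_medium,n_large``.
    """
    rows = []
    for rec in records:
        fs = extract_all(rec)
        rows.append(
            {
                "id": rec.id,
                "lesion_count": fs.lesion_count,
                "lesion_load": fs.lesion_load_voxels,
                "mean_pd": fs.mean_pd_intensity,
                "mean_t2": fs.mean_t2_intensity,
                "mean_dist_center": fs.mean_dist_to_center_mm,
                "central_cube": fs.central_cube_presence,
                "min_axis_dist": fs.min_centroid_axis_dist_mm,
                "n_small": fs.size_profile[0],
                "n_medium": fs.size_profile[1],
                "n_large": fs.size_profile[2],
            }
        )
    return pd.DataFrame(rows, columns=FEATURE_CSV_COLUMNS)
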