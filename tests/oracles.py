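"""Independent brute-force oracles for the lesion features.

Deliberately naive implementations (BFS flood fill, explicit per-voxel
loops) kept independent of the package's vectorised code paths.
"""

from collections import deque

import numpy as np

_OFFSETS = {}
for conn, rule in ((6, lambda s: s == 1), (18, lambda s: s in (1, 2)), (26, lambda s: s >= 1)):
    _OFFSETS[conn] = [
        (dx, dy, dz)
        for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
        if rule(abs(dx) + abs(dy) + abs(dz))
    ]


def bfs_components(mask_arr: np.ndarray, connectivity: int = 18):
    """Partition the nonzero voxels into connected components by BFS.

    Returns a list of voxel-index lists, ordered by first raster appearance.
    """
    arr = np.asarray(mask_arr).astype(bool)
    offsets = _OFFSETS[connectivity]
    seen = np.zeros_like(arr, dtype=bool)
    comps = []
    for idx in np.argwhere(arr):
        start = tuple(idx)
        if seen[start]:
            continue
        comp = []
        q = deque([start])
        seen[start] = True
        while q:
            v = q.popleft()
            comp.append(v)
            for off in offsets:
                nb = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
                if (0 <= nb[0] < arr.shape[0] and 0 <= nb[1] < arr.shape[1]
                        and 0 <= nb[2] < arr.shape[2] and arr[nb] and not seen[nb]):
                    seen[nb] = True
                    q.append(nb)
        comps.append(comp)
    return comps


def oracle_lesion_count(mask_arr):
    return len(bfs_components(mask_arr, 18))


def oracle_lesion_load(mask_arr):
    return int(np.asarray(mask_arr).astype(bool).sum())


def oracle_mean_intensity(mask_arr, vol_arr):
    total, n = 0.0, 0
    arr = np.asarray(mask_arr).astype(bool)
    for idx in np.argwhere(arr):
        total += float(vol_arr[tuple(idx)])
        n += 1
    return total / n


def _center_mm(shape, voxel):
    return tuple((shape[i] // 2) * voxel[i] for i in range(3))


def oracle_mean_distance_to_center(mask_arr, voxel):
    arr = np.asarray(mask_arr).astype(bool)
    cx, cy, cz = _center_mm(arr.shape, voxel)
    dists = []
    for i, j, k in np.argwhere(arr):
        dx = i * voxel[0] - cx
        dy = j * voxel[1] - cy
        dz = k * voxel[2] - cz
        dists.append((dx * dx + dy * dy + dz * dz) ** 0.5)
    return sum(dists) / len(dists)


def oracle_central_cube(mask_arr, voxel, side_mm=10.0):
    arr = np.asarray(mask_arr).astype(bool)
    cx, cy, cz = _center_mm(arr.shape, voxel)
    for i, j, k in np.argwhere(arr):
        if (abs(i * voxel[0] - cx) <= side_mm / 2
                and abs(j * voxel[1] - cy) <= side_mm / 2
                and abs(k * voxel[2] - cz) <= side_mm / 2):
            return 1
    return 0


def oracle_min_centroid_axis_distance(mask_arr, voxel):
    arr = np.asarray(mask_arr).astype(bool)
    cx, cy, _ = _center_mm(arr.shape, voxel)
    best = float("inf")
    for comp in bfs_components(arr, 18):
        xs = [v[0] * voxel[0] for v in comp]
        ys = [v[1] * voxel[1] for v in comp]
        gx = sum(xs) / len(xs)
        gy = sum(ys) / len(ys)
        best = min(best, ((gx - cx) ** 2 + (gy - cy) ** 2) ** 0.5)
    return best


def oracle_size_profile(mask_arr):
    sizes = [len(c) for c in bfs_components(mask_arr, 18)]
    return (sum(1 for s in sizes if s <= 15),
            sum(1 for s in sizes if 16 <= s <= 36),
            sum(1 for s in sizes if s >= 37))


def random_mask(rng: np.random.Generator, max_dim=16, density=0.08) -> np.ndarray:
    dims = tuple(int(rng.integers(3, max_dim + 1)) for _ in range(3))
    return (rng.random(dims) < density).astype(np.uint8)
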