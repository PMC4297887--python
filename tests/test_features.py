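import numpy as np
import pytest

import oracles
from conftest import make_mask
from cispredict import (VoxelGrid3D, central_cube_presence,
                        connected_components, extract_all, extract_cohort,
                        lesion_count, lesion_load, mean_distance_to_center,
                        mean_lesion_intensity, min_centroid_axis_distance,
                        size_profile)
from cispredict.synthetic import CONVERTER, PatientRecord


class TestConnectivity:
    def test_edge_adjacent_voxels_are_one_component_at_18(self):
        m = make_mask((3, 3, 3), [(0, 0, 0), (1, 1, 0)])
        assert connected_components(m, 18).n_components == 1

    def test_corner_adjacency_splits_at_18_joins_at_26(self):
        m = make_mask((3, 3, 3), [(0, 0, 0), (1, 1, 1)])
        assert connected_components(m, 18).n_components == 2
        assert connected_components(m, 26).n_components == 1

    def test_edge_adjacency_splits_at_6(self):
        m = make_mask((3, 3, 3), [(0, 0, 0), (1, 1, 0)])
        assert connected_components(m, 6).n_components == 2

    def test_labels_follow_raster_order(self):
        m = make_mask((4, 4, 4), [(3, 3, 3), (0, 0, 0)])
        lab = connected_components(m, 18).label_grid.values
        assert lab[0, 0, 0] == 1 and lab[3, 3, 3] == 2

    def test_non_binary_mask_rejected(self):
        g = VoxelGrid3D(np.full((2, 2, 2), 2.0))
        with pytest.raises(ValueError):
            connected_components(g, 18)

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_partition_matches_bfs_oracle(self, rng, connectivity):
        """Component partition identical to a breadth-first-search oracle."""
        for _ in range(50):
            arr = oracles.random_mask(rng, max_dim=12)
            m = VoxelGrid3D(arr)
            got = connected_components(m, connectivity)
            comps = oracles.bfs_components(arr, connectivity)
            assert got.n_components == len(comps)
            for k, comp in enumerate(comps, start=1):
                labels = {got.label_grid.values[v] for v in comp}
                assert labels == {k}
            assert got.component_sizes.sum() == arr.sum()


class TestSimpleFeatures:
    def test_single_voxel_counts(self):
        m = make_mask((3, 3, 3), [(1, 1, 1)])
        assert lesion_count(m) == 1
        assert lesion_load(m) == 1

    def test_two_corner_touching_voxels_are_two_lesions(self):
        m = make_mask((3, 3, 3), [(0, 0, 0), (1, 1, 1)])
        assert lesion_count(m) == 2

    def test_load_sums_components(self):
        m = make_mask((8, 8, 3), [(0, 0, 0), (0, 1, 0), (1, 0, 0),
                                  (5, 5, 0), (5, 6, 0), (6, 5, 0), (6, 6, 0)])
        assert lesion_load(m) == 7
        assert lesion_count(m) == 2

    def test_empty_mask_is_an_error_everywhere(self):
        m = VoxelGrid3D(np.zeros((3, 3, 3)))
        vol = VoxelGrid3D(np.ones((3, 3, 3)))
        for fn in (lesion_count, lesion_load, size_profile,
                   mean_distance_to_center, central_cube_presence,
                   min_centroid_axis_distance):
            with pytest.raises(ValueError):
                fn(m)
        with pytest.raises(ValueError):
            mean_lesion_intensity(m, vol)

    def test_mean_intensity_constant_and_average(self):
        m = make_mask((3, 3, 3), [(0, 0, 0), (2, 2, 2)])
        const = VoxelGrid3D(np.full((3, 3, 3), 100.0))
        assert mean_lesion_intensity(m, const) == 100.0
        vol = np.zeros((3, 3, 3))
        vol[0, 0, 0], vol[2, 2, 2] = 10.0, 20.0
        assert mean_lesion_intensity(m, VoxelGrid3D(vol)) == 15.0

    def test_mean_intensity_lattice_mismatch(self):
        m = make_mask((3, 3, 3), [(0, 0, 0)])
        with pytest.raises(ValueError):
            mean_lesion_intensity(m, VoxelGrid3D(np.ones((4, 3, 3))))


class TestDistanceFeatures:
    def test_voxel_at_center_has_zero_distance(self):
        m = make_mask((5, 5, 5), [(2, 2, 2)], voxel_size=(2.0, 2.0, 2.0))
        assert mean_distance_to_center(m) == 0.0
        assert min_centroid_axis_distance(m) == 0.0
        assert central_cube_presence(m) == 1

    def test_distance_uses_mm_not_indices(self):
        # single voxel 3 steps along axis 0 with 2 mm voxels -> 6 mm
        m = make_mask((11, 11, 11), [(5 + 3, 5, 5)], voxel_size=(2.0, 2.0, 2.0))
        assert mean_distance_to_center(m) == pytest.approx(6.0)

    def test_cube_boundary_is_closed(self):
        # 6 mm away on one axis: outside; exactly 5 mm: inside (closed interval)
        m = make_mask((13, 13, 13), [(0, 6, 6)], voxel_size=(1.0, 1.0, 1.0))
        assert central_cube_presence(m) == 0
        m2 = make_mask((13, 13, 13), [(1, 6, 6)])  # exactly 5 mm on axis 0
        assert central_cube_presence(m2) == 1
        m3 = make_mask((13, 13, 13), [(1, 1, 6)])  # 5 mm on two axes, still inside
        assert central_cube_presence(m3) == 1

    def test_cube_requires_positive_side(self):
        m = make_mask((3, 3, 3), [(1, 1, 1)])
        with pytest.raises(ValueError):
            central_cube_presence(m, side_mm=0)

    def test_axis_distance_is_in_plane_minimum(self):
        # two components at in-plane distances 4 mm and 9 mm
        m = make_mask((21, 21, 5), [(10 + 4, 10, 0), (10, 10 + 9, 4)])
        assert min_centroid_axis_distance(m) == pytest.approx(4.0)

    def test_axis_distance_ignores_vertical_offset(self):
        m = make_mask((9, 9, 9), [(4, 4, 0)])  # on the axis, far below center
        assert min_centroid_axis_distance(m) == 0.0


class TestSizeProfile:
    @pytest.mark.parametrize("sizes,expected", [
        ((3, 20, 40), (1, 1, 1)),
        ((15, 16, 36, 37), (1, 2, 1)),  # bin edges: 15 small, 16/36 medium, 37 large
    ])
    def test_bin_edges(self, sizes, expected):
        # build well-separated straight-line components of the given sizes
        dims = (max(sizes) + 2, 3 * len(sizes) + 2, 3)
        voxels = []
        for j, s in enumerate(sizes):
            voxels.extend((i, 3 * j, 0) for i in range(s))
        m = make_mask(dims, voxels)
        assert size_profile(m) == expected
        assert sum(size_profile(m)) == lesion_count(m)


class TestRandomMaskOracles:
    def test_all_features_match_brute_force(self, rng):
        """All eight features agree with naive loop/BFS oracles on random masks."""
        checked = 0
        while checked < 100:
            arr = oracles.random_mask(rng, max_dim=16)
            if arr.sum() == 0:
                continue
            checked += 1
            voxel = tuple(rng.choice([0.5, 1.0, 2.0, 3.0]) for _ in range(3))
            m = VoxelGrid3D(arr, voxel)
            vol = VoxelGrid3D(rng.random(arr.shape) * 100, voxel)
            assert lesion_count(m) == oracles.oracle_lesion_count(arr)
            assert lesion_load(m) == oracles.oracle_lesion_load(arr)
            assert mean_lesion_intensity(m, vol) == pytest.approx(
                oracles.oracle_mean_intensity(arr, vol.values), rel=1e-9)
            assert mean_distance_to_center(m) == pytest.approx(
                oracles.oracle_mean_distance_to_center(arr, voxel), rel=1e-9)
            assert central_cube_presence(m) == oracles.oracle_central_cube(arr, voxel)
            assert min_centroid_axis_distance(m) == pytest.approx(
                oracles.oracle_min_centroid_axis_distance(arr, voxel), rel=1e-9, abs=1e-12)
            assert size_profile(m) == oracles.oracle_size_profile(arr)

    def test_translation_invariance(self, rng):
        """Shifting all lesions leaves count, load and size profile unchanged."""
        for _ in range(20):
            arr = oracles.random_mask(rng, max_dim=10)
            if arr.sum() == 0:
                continue
            pad = np.zeros((arr.shape[0] + 4, arr.shape[1] + 4, arr.shape[2] + 4),
                           dtype=arr.dtype)
            pad[:arr.shape[0], :arr.shape[1], :arr.shape[2]] = arr
            shifted = np.roll(pad, shift=(2, 1, 2), axis=(0, 1, 2))
            m0, m1 = VoxelGrid3D(pad), VoxelGrid3D(shifted)
            vol = VoxelGrid3D(np.ones(pad.shape))
            assert lesion_count(m0) == lesion_count(m1)
            assert lesion_load(m0) == lesion_load(m1)
            assert size_profile(m0) == size_profile(m1)
            assert mean_lesion_intensity(m0, vol) == mean_lesion_intensity(m1, vol)

    def test_adding_a_voxel_never_decreases_load_and_merging_never_increases_count(self, rng):
        for _ in range(20):
            arr = oracles.random_mask(rng, max_dim=10, density=0.1)
            if arr.sum() == 0:
                continue
            free = np.argwhere(arr == 0)
            if len(free) == 0:
                continue
            add = tuple(free[rng.integers(len(free))])
            arr2 = arr.copy()
            arr2[add] = 1
            assert lesion_load(VoxelGrid3D(arr2)) == lesion_load(VoxelGrid3D(arr)) + 1
            # a new voxel can merge components but never split them:
            # count drops by (number of distinct adjacent components - 1), or +1 if isolated
            assert lesion_count(VoxelGrid3D(arr2)) <= lesion_count(VoxelGrid3D(arr)) + 1


class TestExtractAll:
    def _toy_record(self):
        native = make_mask((9, 9, 5), [(4, 4, 2), (4, 5, 2), (5, 4, 2),
                                       (4, 4, 3), (5, 5, 2)],
                           voxel_size=(1.0, 1.0, 2.0))
        template = make_mask((9, 9, 9), [(4, 4, 4)], voxel_size=(2.0, 2.0, 2.0))
        pd_vol = VoxelGrid3D(np.full((9, 9, 5), 50.0), (1.0, 1.0, 2.0))
        t2_vol = VoxelGrid3D(np.full((9, 9, 5), 70.0), (1.0, 1.0, 2.0))
        return PatientRecord(id="T001", native_mask=native, template_mask=template,
                             pd_volume=pd_vol, t2_volume=t2_vol, age=34.0,
                             gender_code=0, cis_type_code=1, edss=1.0,
                             label=CONVERTER, horizon="1y")

    def test_single_central_lesion(self):
        fs = extract_all(self._toy_record())
        assert fs.lesion_count == 1
        assert fs.lesion_load_voxels == 5
        assert fs.mean_pd_intensity == 50.0
        assert fs.mean_t2_intensity == 70.0
        assert fs.central_cube_presence == 1
        assert fs.mean_dist_to_center_mm == 0.0
        assert fs.min_centroid_axis_dist_mm == 0.0
        assert fs.size_profile == (1, 0, 0)

    def test_composition_matches_individual_ops(self):
        rec = self._toy_record()
        fs = extract_all(rec)
        assert fs.lesion_count == lesion_count(rec.native_mask)
        assert fs.lesion_load_voxels == lesion_load(rec.native_mask)
        assert fs.mean_pd_intensity == mean_lesion_intensity(rec.native_mask, rec.pd_volume)
        assert fs.mean_t2_intensity == mean_lesion_intensity(rec.native_mask, rec.t2_volume)
        assert fs.mean_dist_to_center_mm == mean_distance_to_center(rec.template_mask)
        assert fs.central_cube_presence == central_cube_presence(rec.template_mask)
        assert fs.min_centroid_axis_dist_mm == min_centroid_axis_distance(rec.template_mask)
        assert fs.size_profile == size_profile(rec.native_mask)

    def test_batch_extraction_one_row_per_patient(self):
        recs = [self._toy_record() for _ in range(3)]
        for i, r in enumerate(recs):
            r.id = f"T{i:03d}"
        table = extract_cohort(recs)
        assert len(table) == 3
        assert list(table["id"]) == ["T000", "T001", "T002"]
        assert table.columns[0] == "id" and "min_axis_dist" in table.columns
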