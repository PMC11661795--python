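import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import ndimage as ndi

from flycount3d import (
    Dopa3DParams,
    LabelVolume,
    SeedSet,
    StackRecipe,
    VoxelGrid,
    closing_3d,
    extract_seeds,
    hminima_transform,
    make_cell_stack,
    measure,
    median_filter_3d,
    reconstruct_by_erosion,
    regional_minima,
    segment_dopa3d,
    suppress_dark,
    watershed_3d,
)
from flycount3d.volio import check_connected_labels

from conftest import grid_1d


def brute_force_reconstruction(marker, mask, connectivity):
    """Independent oracle: literally iterate erode-then-max to stability."""
    footprint = ndi.generate_binary_structure(3, 3 if connectivity == 26 else 1)
    cur = np.asarray(marker, dtype=float)
    mask = np.asarray(mask, dtype=float)
    while True:
        eroded = ndi.grey_erosion(cur, footprint=footprint, mode="nearest")
        nxt = np.maximum(eroded, mask)
        if np.array_equal(nxt, cur):
            return cur
        cur = nxt


def count_minima(volume, connectivity=26):
    mask = regional_minima(volume, connectivity)
    _, n = ndi.label(mask, structure=ndi.generate_binary_structure(3, 3))
    return n


F = np.array([5, 2, 5, 1, 5], dtype=float).reshape(1, 1, 5)


class TestReconstructionByErosion:
    def test_fixed_point_marker_equals_mask(self):
        out = reconstruct_by_erosion(F, F, 26)
        np.testing.assert_array_equal(out, F)

    @pytest.mark.parametrize(
        "offset, expected",
        [(2, [5, 4, 5, 3, 5]), (3, [5, 5, 5, 4, 5])],
    )
    def test_hand_iterated_1d_examples(self, offset, expected):
        out = reconstruct_by_erosion(F + offset, F, 26)
        np.testing.assert_array_equal(out.ravel(), expected)

    def test_marker_below_mask_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_by_erosion(F - 1, F, 26)

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_brute_force_on_random_volumes(self, connectivity):
        rng = np.random.default_rng(42)
        for _ in range(60):
            shape = tuple(rng.integers(2, 7, 3))
            mask = rng.integers(0, 10, shape).astype(float)
            marker = mask + rng.integers(0, 5, shape)
            out = reconstruct_by_erosion(marker, mask, connectivity)
            ref = brute_force_reconstruction(marker, mask, connectivity)
            np.testing.assert_array_equal(out, ref)

    def test_bounded_between_mask_and_marker(self):
        rng = np.random.default_rng(7)
        mask = rng.integers(0, 20, (5, 5, 5)).astype(float)
        marker = mask + rng.integers(0, 8, (5, 5, 5))
        out = reconstruct_by_erosion(marker, mask, 26)
        assert (out >= mask).all() and (out <= marker).all()


class TestHMinima:
    def test_identity_at_h_zero(self):
        np.testing.assert_array_equal(hminima_transform(F, 0, 26), F)

    @pytest.mark.parametrize(
        "h, expected, n_minima",
        [(2, [5, 4, 5, 3, 5], 2), (3, [5, 5, 5, 4, 5], 1)],
    )
    def test_worked_examples_and_minima_counts(self, h, expected, n_minima):
        out = hminima_transform(F, h, 26)
        np.testing.assert_array_equal(out.ravel(), expected)
        assert count_minima(out) == n_minima

    @settings(max_examples=30, deadline=None)
    @given(
        data=hnp.arrays(
            np.int64,
            hnp.array_shapes(min_dims=3, max_dims=3, min_side=2, max_side=6),
            elements=st.integers(0, 15),
        ),
        h1=st.integers(0, 6),
        dh=st.integers(0, 6),
    )
    def test_minima_count_non_increasing_in_h(self, data, h1, dh):
        f = data.astype(float)
        n1 = count_minima(hminima_transform(f, h1, 26))
        n2 = count_minima(hminima_transform(f, h1 + dh, 26))
        assert n2 <= n1


class TestPreprocessing:
    def test_median_constant_unchanged_and_radius0_identity(self):
        grid = VoxelGrid(np.full((4, 4, 4), 7, np.uint8))
        np.testing.assert_array_equal(median_filter_3d(grid, 1).data, grid.data)
        assert median_filter_3d(grid, 0) is grid

    def test_median_removes_isolated_bright_voxel(self):
        data = np.zeros((5, 5, 5), np.uint8)
        data[2, 2, 2] = 255
        out = median_filter_3d(VoxelGrid(data), 1)
        assert out.data[2, 2, 2] == 0

    def test_closing_fills_one_voxel_pit(self):
        data = np.full((5, 5, 5), 255, np.uint8)
        data[2, 2, 2] = 0
        out = closing_3d(VoxelGrid(data), 1)
        assert out.data[2, 2, 2] == 255

    @settings(max_examples=20, deadline=None)
    @given(
        data=hnp.arrays(
            np.uint8,
            hnp.array_shapes(min_dims=3, max_dims=3, min_side=3, max_side=7),
            elements=st.integers(0, 255),
        )
    )
    def test_closing_is_extensive_and_idempotent(self, data):
        grid = VoxelGrid(data)
        once = closing_3d(grid, 1)
        assert (once.data >= grid.data).all()
        twice = closing_3d(once, 1)
        np.testing.assert_array_equal(twice.data, once.data)

    def test_suppress_dark_rule(self):
        grid = grid_1d([10, 80, 200])
        out = suppress_dark(grid, 75)
        assert list(out.data.ravel()) == [0, 80, 200]
        np.testing.assert_array_equal(suppress_dark(grid, 0).data, grid.data)


class TestRegionalMinima:
    def test_increasing_ramp_marks_first_voxel(self):
        ramp = np.arange(1, 8, dtype=float).reshape(1, 1, 7)
        mask = regional_minima(ramp, 26)
        assert mask[0, 0, 0] and mask.sum() == 1

    def test_constant_volume_is_one_plateau_minimum(self):
        assert regional_minima(np.zeros((3, 3, 3)), 26).all()


class TestSeedsAndWatershed:
    def test_uniform_volume_degenerate_single_seed(self):
        grid = VoxelGrid(np.full((4, 4, 4), 50, np.uint8))
        with pytest.warns(UserWarning, match="uniform"):
            seeds = extract_seeds(grid, Dopa3DParams(invert=False, h=0, min_seed_voxels=1))
        assert seeds.n_seeds == 1

    def test_two_separated_bright_spheres_two_seeds(self, clean_stack_20):
        grid, truth, _ = clean_stack_20
        seeds = extract_seeds(grid, Dopa3DParams())
        assert seeds.n_seeds == truth.n_labels

    def test_noisy_minima_within_one_cell_merged_by_h(self):
        # one bright blob whose interior has three small bright peaks:
        # in the inverted relief these are three minima of dynamic 5
        data = np.full((5, 9, 9), 10, np.uint8)
        data[1:4, 2:7, 2:7] = 200
        for pos in ((2, 3, 3), (2, 5, 5), (2, 3, 6)):
            data[pos] = 205
        grid = VoxelGrid(data)
        params = Dopa3DParams(h=10, min_seed_voxels=1)
        seeds = extract_seeds(grid, params)
        assert seeds.n_seeds == 1
        shallow = extract_seeds(grid, Dopa3DParams(h=2, min_seed_voxels=1))
        assert shallow.n_seeds == 3

    def test_1d_two_basin_flood(self):
        relief = np.array([0, 5, 0], dtype=float).reshape(1, 1, 3)
        seed_labels = np.array([1, 0, 2], dtype=np.int32).reshape(1, 1, 3)
        out = watershed_3d(relief, SeedSet(seed_labels, 2), None, 6)
        flat = out.labels.ravel()
        assert flat[0] == 1 and flat[2] == 2 and flat[1] in (1, 2)

    def test_single_seed_full_mask(self):
        relief = np.random.default_rng(0).random((4, 4, 4))
        seed_labels = np.zeros((4, 4, 4), np.int32)
        seed_labels[2, 2, 2] = 1
        out = watershed_3d(relief, SeedSet(seed_labels, 1), np.ones((4, 4, 4), bool), 6)
        assert (out.labels == 1).all()

    def test_empty_seed_set_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="empty seed"):
            out = watershed_3d(np.zeros((3, 3, 3)), SeedSet(np.zeros((3, 3, 3), np.int32), 0))
        assert out.n_labels == 0

    def test_seed_outside_mask_rejected(self):
        seeds = np.zeros((3, 3, 3), np.int32)
        seeds[0, 0, 0] = 1
        mask = np.ones((3, 3, 3), bool)
        mask[0, 0, 0] = False
        with pytest.raises(ValueError, match="mask"):
            watershed_3d(np.zeros((3, 3, 3)), SeedSet(seeds, 1), mask)

    def test_partition_invariants_random_volumes(self):
        """Regions partition the mask, are connected, and contain their seed."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            relief = rng.integers(0, 10, (6, 8, 8)).astype(float)
            minima = regional_minima(relief, 26)
            seed_labels, n = ndi.label(minima, structure=ndi.generate_binary_structure(3, 3))
            mask = ndi.binary_dilation(seed_labels > 0, iterations=2)
            out = watershed_3d(relief, SeedSet(seed_labels, n), mask, 6)
            assert ((out.labels > 0) == mask).all()
            assert check_connected_labels(out, connectivity=6)
            for lab in range(1, n + 1):
                wanted = np.unique(out.labels[seed_labels == lab])
                assert len(wanted) == 1 and wanted[0] > 0


class TestMeasure:
    def test_single_voxel_centroid_in_um(self):
        labels = np.zeros((5, 6, 7), np.int32)
        labels[2, 3, 4] = 1
        grid = VoxelGrid(np.zeros((5, 6, 7), np.uint8), dz=1, dy=0.5, dx=0.5)
        table = measure(LabelVolume(labels, 1), grid)
        row = table.iloc[0]
        assert (row.centroid_z, row.centroid_y, row.centroid_x) == (2.0, 1.5, 2.0)

    def test_empty_labels_empty_table(self):
        grid = VoxelGrid(np.zeros((3, 3, 3), np.uint8))
        table = measure(LabelVolume(np.zeros((3, 3, 3), np.int32), 0), grid)
        assert len(table) == 0

    def test_volume_is_voxels_times_unit_volume(self):
        labels = np.zeros((4, 5, 5), np.int32)
        labels[0, :2, :5] = 1  # 10 voxels
        labels[2:4, :2, :5] = 2  # 20 voxels
        grid = VoxelGrid(np.zeros((4, 5, 5), np.uint8))
        table = measure(LabelVolume(labels, 2), grid)
        assert list(table.volume_um3) == [10.0, 20.0]

    def test_shape_mismatch_rejected(self):
        grid = VoxelGrid(np.zeros((3, 3, 3), np.uint8))
        with pytest.raises(ValueError):
            measure(LabelVolume(np.zeros((3, 3, 4), np.int32), 0), grid)


class TestFullPipeline:
    def test_blank_stack_zero_cells(self):
        grid = VoxelGrid(np.zeros((6, 16, 16), np.uint8))
        labels, table = segment_dopa3d(grid)
        assert labels.n_labels == 0 and len(table) == 0

    def test_recovers_clean_non_touching_count(self, clean_stack_20):
        grid, truth, _ = clean_stack_20
        labels, table = segment_dopa3d(grid)
        assert labels.n_labels == truth.n_labels == 20
        assert len(table) == 20

    def test_touching_pairs_all_split(self):
        recipe = StackRecipe(
            shape=(24, 160, 160), n_cells=10, touching_fraction=1.0,
            noise="none", rng_seed=21,
        )
        grid, truth, _ = make_cell_stack(recipe)
        labels, _ = segment_dopa3d(grid)
        assert labels.n_labels == truth.n_labels == 10

    def test_each_region_contains_one_true_centroid(self, noisy_stack_20):
        grid, truth, truth_table = noisy_stack_20
        labels, _ = segment_dopa3d(grid)
        hits = []
        for row in truth_table.itertuples():
            idx = (
                int(round(row.centroid_z / grid.dz)),
                int(round(row.centroid_y / grid.dy)),
                int(round(row.centroid_x / grid.dx)),
            )
            hits.append(labels.labels[idx])
        hits = [h for h in hits if h > 0]
        assert len(set(hits)) == truth.n_labels  # one region per true cell

    def test_intensity_offset_equivariance(self, clean_stack_20):
        grid, _, _ = clean_stack_20
        offset = 30
        shifted = VoxelGrid(
            (grid.data.astype(np.uint16) + offset).astype(np.uint8),
            *grid.spacing, bit_depth=8,
        )
        base = Dopa3DParams()
        shifted_params = Dopa3DParams(dark_threshold=base.dark_threshold + offset)
        labels_a, _ = segment_dopa3d(grid, base)
        labels_b, _ = segment_dopa3d(shifted, shifted_params)
        np.testing.assert_array_equal(labels_a.labels, labels_b.labels)

    def test_deterministic_across_runs(self, noisy_stack_20):
        grid, _, _ = noisy_stack_20
        labels_a, table_a = segment_dopa3d(grid)
        labels_b, table_b = segment_dopa3d(grid)
        np.testing.assert_array_equal(labels_a.labels, labels_b.labels)
        assert table_a.equals(table_b)
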