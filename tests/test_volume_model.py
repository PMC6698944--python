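"""Core primitives: region stats, uniformity, region growing, components."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mr2sct.volume_model import (
    IntensityVolume,
    IntensityWindow,
    compute_region_stats,
    compute_uniformity,
    connected_components,
    region_grow,
)

from _oracles import flood_fill_components, flood_fill_grow


def vol(data, spacing=(1.0, 1.0, 1.0)):
    return IntensityVolume(data=np.asarray(data, float), spacing_mm=spacing)


class TestRegionStats:
    def test_two_point_population_sd(self):
        v = vol(np.array([[[2.0, 4.0]]]))
        s = compute_region_stats(v, np.ones((1, 1, 2), bool))
        assert (s.mean, s.sd, s.min, s.n) == (3.0, 1.0, 2.0, 2)

    def test_constant_region(self):
        v = vol(np.full((1, 1, 3), 5.0))
        s = compute_region_stats(v, np.ones((1, 1, 3), bool))
        assert (s.mean, s.sd, s.min) == (5.0, 0.0, 5.0)

    def test_empty_mask_errors(self):
        v = vol(np.zeros((2, 2, 2)))
        with pytest.raises(ValueError, match="empty region"):
            compute_region_stats(v, np.zeros((2, 2, 2), bool))


class TestUniformity:
    def test_two_values(self):
        v = vol(np.array([[[2.0, 4.0]]]))
        assert compute_uniformity(v, (0, 0, 0), (0.0, 0.0, 3.0)) == pytest.approx(3.0)

    def test_constant_window_is_infinitely_uniform(self):
        v = vol(np.full((3, 3, 3), 7.0))
        assert compute_uniformity(v, (1, 1, 1), 3.0) == math.inf

    def test_hand_computed_window(self):
        # window values {10, 10, 10, 14}: mean 11, population sd sqrt(3)
        v = vol(np.array([[[10.0, 10.0], [10.0, 14.0]]]))
        u = compute_uniformity(v, (0, 0, 0), (0.0, 3.0, 3.0))
        assert u == pytest.approx(11.0 / math.sqrt(3.0))

    def test_center_outside_grid_errors(self):
        v = vol(np.zeros((2, 2, 2)))
        with pytest.raises(ValueError, match="outside grid"):
            compute_uniformity(v, (5, 0, 0), 3.0)

    @given(c=st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(7)
        data = rng.uniform(1.0, 10.0, size=(5, 5, 5))
        u1 = compute_uniformity(vol(data), (2, 2, 2), 3.0)
        u2 = compute_uniformity(vol(data * c), (2, 2, 2), 3.0)
        assert u2 == pytest.approx(u1, rel=1e-9)


class TestRegionGrow:
    def test_uniform_block_fully_grown(self):
        v = vol(np.full((4, 4, 4), 5.0))
        out = region_grow(v, [(0, 0, 0)], IntensityWindow(4, 6))
        assert out.all()

    def test_out_of_window_shell_confines_growth(self):
        data = np.full((5, 5, 5), 100.0)
        data[1:4, 1:4, 1:4] = 5.0
        out = region_grow(vol(data), [(2, 2, 2)], IntensityWindow(0, 10))
        expected = np.zeros((5, 5, 5), bool)
        expected[1:4, 1:4, 1:4] = True
        assert np.array_equal(out, expected)

    def test_one_voxel_wall_separates_blobs(self):
        data = np.zeros((1, 3, 7))
        data[0, :, :3] = 5.0
        data[0, :, 3] = 100.0  # wall
        data[0, :, 4:] = 5.0
        out = region_grow(vol(data), [(0, 1, 1)], IntensityWindow(0, 10))
        oracle = flood_fill_grow(data, [(0, 1, 1)], 0, 10)
        assert np.array_equal(out, oracle)
        assert not out[0, :, 4:].any()

    def test_seed_outside_window_errors(self):
        v = vol(np.full((2, 2, 2), 50.0))
        with pytest.raises(ValueError, match="seed outside intensity window"):
            region_grow(v, [(0, 0, 0)], IntensityWindow(0, 10))

    def test_seed_on_barrier_errors(self):
        v = vol(np.full((2, 2, 2), 5.0))
        barrier = np.zeros((2, 2, 2), bool)
        barrier[0, 0, 0] = True
        with pytest.raises(ValueError, match="seed inside barrier"):
            region_grow(v, [(0, 0, 0)], IntensityWindow(0, 10), barrier=barrier)

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(42)
        for _ in range(25):
            shape = tuple(rng.integers(3, 12, size=3))
            data = rng.integers(0, 5, size=shape).astype(float)
            barrier = rng.random(shape) < 0.15
            lo, hi = 1.0, 3.0
            ok = (data >= lo) & (data <= hi) & ~barrier
            if not ok.any():
                continue
            seed = tuple(np.argwhere(ok)[0])
            out = region_grow(
                vol(data), [seed], IntensityWindow(lo, hi), barrier, connectivity
            )
            oracle = flood_fill_grow(data, [seed], lo, hi, barrier, connectivity)
            assert np.array_equal(out, oracle)

    def test_window_monotonicity(self):
        """Enlarging the intensity window never shrinks the grown set."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            data = rng.integers(0, 6, size=(8, 8, 8)).astype(float)
            data[4, 4, 4] = 2.0
            small = region_grow(vol(data), [(4, 4, 4)], IntensityWindow(2, 3))
            big = region_grow(vol(data), [(4, 4, 4)], IntensityWindow(1, 4))
            assert (small & ~big).sum() == 0


class TestConnectedComponents:
    def test_single_cube(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[1:3, 1:3, 1:3] = True
        _, sizes = connected_components(mask)
        assert sizes == {1: 8}

    def test_diagonal_voxels_connectivity(self):
        mask = np.zeros((2, 2, 2), bool)
        mask[0, 0, 0] = mask[1, 1, 1] = True
        assert len(connected_components(mask, 6)[1]) == 2
        assert len(connected_components(mask, 26)[1]) == 1

    def test_checkerboard_matches_oracle(self):
        yy, xx = np.mgrid[0:3, 0:3]
        board = (yy + xx) % 2 == 0  # 5 isolated cells under 4-connectivity
        _, sizes = connected_components(board, 6)
        oracle = flood_fill_components(board, 6)
        assert len(sizes) == len(oracle) == 5
        assert sorted(sizes.values()) == sorted(len(c) for c in oracle)

    def test_sizes_sum_to_true_count(self):
        rng = np.random.default_rng(11)
        mask = rng.random((10, 10, 10)) < 0.4
        _, sizes = connected_components(mask, 26)
        assert sum(sizes.values()) == int(mask.sum())
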