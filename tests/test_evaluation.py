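"""Dice, ME/MAE, evaluation regions and external bone contour distance."""

import math

import numpy as np
import pytest

from mr2sct.evaluation import (
    build_eval_regions,
    dice,
    ed_errors,
    evaluate,
    external_bone_contour_distance,
)
from mr2sct.volume_model import IntensityVolume


def ct(data, spacing=(1.0, 1.0, 1.0)):
    return IntensityVolume(np.asarray(data, float), spacing, modality="CT")


def skull_volume(shift=0):
    """A hollow bone box in an air bath, optionally shifted along x."""
    data = np.full((24, 24, 24), -1000.0)
    data[4:20, 4:20, 4 + shift : 20 + shift] = 50.0
    data[6:18, 6:18, 6 + shift : 18 + shift] = 400.0
    data[8:16, 8:16, 8 + shift : 16 + shift] = 50.0
    return ct(data)


class TestDice:
    def test_identical_nonempty(self):
        m = np.zeros((4, 4, 4), bool)
        m[1:3] = True
        assert dice(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0], b[2] = True, True
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros((1, 1, 8), bool)
        b = np.zeros((1, 1, 8), bool)
        a[0, 0, :4] = True
        b[0, 0, 2:6] = True  # |A|=|B|=4, overlap 2
        assert dice(a, b) == 0.5

    def test_symmetric_and_empty(self):
        rng = np.random.default_rng(0)
        a = rng.random((5, 5, 5)) < 0.3
        b = rng.random((5, 5, 5)) < 0.3
        assert dice(a, b) == dice(b, a)
        assert dice(np.zeros((2, 2, 2), bool), np.zeros((2, 2, 2), bool)) == 1.0

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            dice(np.zeros((2, 2, 2), bool), np.zeros((3, 3, 3), bool))


class TestEdErrors:
    def test_identical_volumes(self):
        v = ct(np.full((3, 3, 3), 100.0))
        assert ed_errors(v, v, np.ones((3, 3, 3), bool)) == (0.0, 0.0)

    def test_signed_vs_absolute(self):
        a = ct(np.array([[[0.0, 10.0]]]))
        b = ct(np.array([[[5.0, 5.0]]]))
        me, mae = ed_errors(b, a, np.ones((1, 1, 2), bool))
        assert me == 0.0 and mae == 5.0

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(-1000, 2000, size=(10, 10, 10))
        b = rng.uniform(-1000, 2000, size=(10, 10, 10))
        region = np.ones(a.shape, bool)
        me, mae = ed_errors(ct(b), ct(a), region)
        diffs = []
        abss = []
        for z in range(10):
            for y in range(10):
                for x in range(10):
                    d = a[z, y, x] - b[z, y, x]
                    diffs.append(d)
                    abss.append(abs(d))
        assert me == pytest.approx(math.fsum(diffs) / 1000.0, rel=1e-12)
        assert mae == pytest.approx(math.fsum(abss) / 1000.0, rel=1e-12)

    def test_mae_bounds_me(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = ct(rng.normal(0, 300, size=(6, 6, 6)))
            b = ct(rng.normal(0, 300, size=(6, 6, 6)))
            me, mae = ed_errors(a, b, np.ones((6, 6, 6), bool))
            assert mae >= abs(me)

    def test_empty_region_errors(self):
        v = ct(np.zeros((2, 2, 2)))
        with pytest.raises(ValueError, match="empty region"):
            ed_errors(v, v, np.zeros((2, 2, 2), bool))


class TestContourDistance:
    def test_identical_volumes_zero_distance(self):
        v = skull_volume()
        out = external_bone_contour_distance(v, v)
        assert out["mean"] == 0.0
        assert out["axial"] == out["coronal"] == out["sagittal"] == 0.0

    def test_one_voxel_shift_along_x(self):
        # a bone plate normal to x: every axial contour voxel moves exactly
        # one voxel when the CT is shifted one voxel along x
        def plate(col):
            data = np.full((24, 24, 24), -1000.0)
            data[4:20, 4:20, col] = 400.0
            return ct(data)

        out = external_bone_contour_distance(plate(12), plate(13))
        assert out["axial"] == pytest.approx(1.0)
        assert out["coronal"] == pytest.approx(1.0)
        assert out["sagittal"] == pytest.approx(0.0)  # per-volume slice choice

    def test_directed_measure_is_asymmetric(self):
        small = skull_volume()
        big = ct(np.full((24, 24, 24), -1000.0))
        big.data[2:22, 2:22, 2:22] = 400.0  # much larger bone blob
        d_ab = external_bone_contour_distance(small, big)["mean"]
        d_ba = external_bone_contour_distance(big, small)["mean"]
        assert d_ab != d_ba

    def test_no_bone_errors(self):
        empty = ct(np.full((8, 8, 8), -1000.0))
        with pytest.raises(ValueError, match="no bone"):
            external_bone_contour_distance(empty, empty)


class TestRegions:
    def test_boundary_rules(self):
        sct = ct(np.array([[[-1000.0, 150.0, 200.0, 0.0]]]))
        ctv = ct(np.array([[[-500.0, 150.0, 200.0, 0.0]]]))
        regions = build_eval_regions(sct, ctv)
        assert not regions["air"][0, 0, 0]  # air in one volume only
        assert regions["soft_tissue"][0, 0, 1]  # 150 HU inside body
        assert regions["bone"][0, 0, 2]  # 200 HU belongs to bone
        assert not regions["soft_tissue"][0, 0, 2]

    def test_empty_body_errors(self):
        v = ct(np.full((2, 2, 2), -1000.0))
        with pytest.raises(ValueError, match="empty whole-body"):
            build_eval_regions(v, v)


class TestPhantomEvaluation:
    def test_sct_vs_truth_ct_contour_distance_small(self, ph_small_noisy, run_small_noisy):
        out = external_bone_contour_distance(run_small_noisy.sct, ph_small_noisy.ct)
        # shared geometry: within one voxel diagonal (1.5 mm spacing)
        assert out["mean"] <= np.sqrt(2.0) * 1.5

    def test_full_report_runs(self, ph_small_noisy, run_small_noisy):
        report = evaluate(
            run_small_noisy.sct, ph_small_noisy.ct, run_small_noisy.labels
        )
        errors = report.ed_errors
        assert set(errors) >= {"whole_body", "air", "soft_tissue", "bone"}
        for vals in errors.values():
            assert vals["mae_hu"] >= abs(vals["me_hu"])
        assert report.dice["bone"] > 0.9
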