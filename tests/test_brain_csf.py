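"""White-matter reference, edges with gap closing, brain/CSF/skull growing."""

import numpy as np
import pytest
from scipy import ndimage

from mr2sct.brain_csf import (
    BrainReference,
    close_edge_gaps_2d,
    detect_and_close_edges,
    find_csf_reference,
    find_wm_reference,
    segment_brain_initial,
    segment_csf,
)
from mr2sct.volume_model import (
    IntensityVolume,
    IntensityWindow,
    Label,
    TissueStats,
    region_grow,
)

from conftest import dice_masks


def mr(data, spacing=(1.0, 1.0, 1.0)):
    return IntensityVolume(np.asarray(data, float), spacing, modality="MR")


def make_ref(wm=1000.0, voxel=(0, 0, 0)):
    return BrainReference(
        wm_voxel=voxel,
        wm_intensity=wm,
        window_stat=IntensityWindow(0.53 * wm, 1.35 * wm),
        window_grow=IntensityWindow(0.7 * wm, 1.2 * wm),
    )


class TestWmReference:
    def _scene(self, wm_mean=1000.0, wm_sd=5.0, gm_sd=30.0, seed=0):
        """WM and GM blobs crossing the middle coronal slice."""
        rng = np.random.default_rng(seed)
        data = np.zeros((40, 40, 40))
        body = np.zeros((40, 40, 40), bool)
        body[5:35, 5:35, 5:35] = True
        data[body] = rng.normal(700.0, gm_sd, size=int(body.sum()))  # GM bath
        wm = np.zeros_like(body)
        wm[8:28, 10:30, 8:28] = True
        data[wm] = rng.normal(wm_mean, wm_sd, size=int(wm.sum()))
        return mr(data), body

    def test_wm_intensity_recovered(self):
        v, body = self._scene()
        ref = find_wm_reference(v, body)
        assert 985.0 <= ref.wm_intensity <= 1015.0

    def test_tie_broken_by_larger_mean(self):
        data = np.full((40, 40, 40), 700.0)
        body = np.ones((40, 40, 40), bool)
        data[5:15, :, 5:15] = 900.0  # perfectly uniform region A
        data[25:35, :, 25:35] = 1000.0  # perfectly uniform region B
        ref = find_wm_reference(mr(data), body)
        assert ref.wm_intensity == 1000.0

    def test_stat_window_is_exact_multiple(self):
        v, body = self._scene()
        ref = find_wm_reference(v, body)
        assert ref.window_stat.lo == 0.53 * ref.wm_intensity
        assert ref.window_stat.hi == 1.35 * ref.wm_intensity
        assert ref.window_grow.lo == 0.7 * ref.wm_intensity

    def test_empty_body_slice_errors(self):
        v, _ = self._scene()
        with pytest.raises(ValueError, match="middle coronal"):
            find_wm_reference(v, np.zeros(v.shape, bool))


class TestEdges:
    def test_clean_disc_rim_detected_and_tight(self):
        yy, xx = np.mgrid[0:48, 0:48]
        disc = (yy - 24) ** 2 + (xx - 24) ** 2 <= 15**2
        data = np.zeros((3, 48, 48))
        data[1][disc] = 1000.0
        edges = detect_and_close_edges(mr(data), make_ref())
        rim = edges[1]
        assert rim.any()
        # edge voxels hug the disc boundary (within 2 voxels of it)
        dist = ndimage.distance_transform_edt(disc) + ndimage.distance_transform_edt(~disc)
        assert dist[rim].max() <= 3.0

    def test_gap_closing_seals_broken_rim(self):
        yy, xx = np.mgrid[0:40, 0:40]
        r = np.hypot(yy - 20, xx - 20)
        rim = (r >= 12) & (r < 13.5)
        rim[18:23, 32:] = False  # knock a multi-voxel gap into the ring
        closed = close_edge_gaps_2d(rim, max_gap_vox=10.0)
        # flood fill from the border must not reach the center
        outside = ~closed
        labeled, _ = ndimage.label(outside)
        assert labeled[0, 0] != labeled[20, 20]

    def test_all_zero_slice_has_no_edges(self):
        edges = detect_and_close_edges(mr(np.zeros((2, 20, 20))), make_ref())
        assert not edges.any()


class TestBrainInitial:
    def test_window_endpoint_included(self):
        data = np.full((1, 1, 3), 1000.0)
        data[0, 0, 2] = 700.0  # exactly 0.7 x wmIntensity
        out = segment_brain_initial(
            mr(data), make_ref(1000.0, (0, 0, 0)), np.zeros(data.shape, bool)
        )
        assert out[0, 0, 2]

    def test_seed_outside_window_errors(self):
        data = np.full((2, 2, 2), 100.0)
        with pytest.raises(ValueError, match="seed outside"):
            segment_brain_initial(
                mr(data), make_ref(1000.0, (0, 0, 0)), np.zeros(data.shape, bool)
            )

    def test_edge_barrier_blocks_inwindow_bridge(self):
        data = np.full((1, 3, 7), 0.0)
        data[0, :, :3] = 1000.0  # brain
        data[0, :, 3] = 800.0  # in-window bridge (e.g. trabecular bone)
        data[0, :, 4:] = 1000.0  # bone-side tissue
        edges = np.zeros(data.shape, bool)
        edges[0, :, 3] = True
        out = segment_brain_initial(mr(data), make_ref(1000.0, (0, 1, 1)), edges)
        assert out[0, :, :3].all()
        assert not out[0, :, 4:].any()


class TestCsfReference:
    def test_phantom_ventricle_found(self, ph_small_clean, run_small_clean):
        stats = run_small_clean.stats["csf"]
        assert 185.0 <= stats.mean <= 215.0

    def test_no_dark_voxel_errors(self):
        data = np.full((20, 20, 20), 1000.0)
        brain0 = np.zeros(data.shape, bool)
        brain0[5:15, 5:15, 5:15] = True
        with pytest.raises(ValueError, match="no CSF reference"):
            find_csf_reference(mr(data), brain0, make_ref(1000.0))

    def test_most_uniform_window_wins(self):
        rng = np.random.default_rng(5)
        data = np.full((24, 24, 24), 1000.0)
        brain0 = np.zeros(data.shape, bool)
        brain0[2:22, 2:22, 2:22] = True
        data[6:11, 6:11, 6:11] = rng.normal(200.0, 20.0, (5, 5, 5))  # noisy CSF
        data[6:11, 14:19, 14:19] = rng.normal(200.0, 5.0, (5, 5, 5))  # uniform CSF
        stats, seeds = find_csf_reference(mr(data), brain0, make_ref(1000.0))
        assert seeds[8, 16, 16] and not seeds[8, 8, 8]
        assert stats.sd < 10.0


class TestCsfGrowing:
    def test_seed_inside_skull_mask_errors(self):
        data = np.full((3, 3, 3), 200.0)
        skull = np.ones(data.shape, bool)
        seeds = np.zeros(data.shape, bool)
        seeds[1, 1, 1] = True
        with pytest.raises(ValueError, match="seed in skull mask"):
            segment_csf(mr(data), TissueStats(200, 10, 180, 27), skull, seeds)

    def test_zero_sd_degenerates_to_exact_intensity(self):
        data = np.full((1, 1, 5), 200.0)
        data[0, 0, 3] = 201.0
        seeds = np.zeros(data.shape, bool)
        seeds[0, 0, 0] = True
        out = segment_csf(
            mr(data), TissueStats(200, 0, 200, 8), np.zeros(data.shape, bool), seeds
        )
        assert out[0, 0, :3].all() and not out[0, 0, 3:].any()

    def test_barrier_respected(self):
        data = np.full((1, 1, 5), 200.0)
        skull = np.zeros(data.shape, bool)
        skull[0, 0, 2] = True
        seeds = np.zeros(data.shape, bool)
        seeds[0, 0, 0] = True
        out = segment_csf(
            mr(data), TissueStats(200, 10, 180, 27), skull, seeds
        )
        assert not out[0, 0, 2:].any()


class TestPipelineBrainMasks:
    def test_disjointness_invariants(self, run_small_noisy):
        m = run_small_noisy.masks
        assert not (m["brain"] & m["csf"]).any()
        assert not (m["brain"] & m["skull"]).any()

    def test_initial_brain_recovers_white_matter(self, ph_small_noisy):
        from mr2sct import air_mask as am, soft_tissue_seg
        from mr2sct import phantom as pm

        p = ph_small_noisy
        roi = am.interpolate_contours(p.contours, p.mr)
        stats = am.estimate_air_stats(p.mr, roi)
        body = soft_tissue_seg.external_body_contour(p.mr, stats)
        ref = find_wm_reference(p.mr, body)
        edges = detect_and_close_edges(p.mr, ref)
        brain0 = segment_brain_initial(p.mr, ref, edges)
        wm_truth = p.regions == pm.REGIONS["wm"]
        assert dice_masks(brain0 & wm_truth, wm_truth) >= 0.95
        # growing never escapes the brain
        assert not (brain0 & ~(p.truth.labels == int(Label.BRAIN))).any()

    def test_scalp_and_face_inside_skull_exclusion_zone(
        self, ph_small_noisy, run_small_noisy
    ):
        from mr2sct import phantom as pm

        skull = run_small_noisy.masks["skull"]
        fat = ph_small_noisy.regions == pm.REGIONS["fat"]
        muscle = ph_small_noisy.regions == pm.REGIONS["muscle"]
        assert (skull & fat).sum() / fat.sum() > 0.95
        assert (skull & muscle).sum() / muscle.sum() > 0.95

    def test_skull_defect_does_not_leak_brain(self):
        from mr2sct import phantom as pm, pipeline as pl

        cfg = pm.PhantomConfig(
            shape=(128,) * 3, spacing_mm=(1.5,) * 3, skull_defect=True
        )
        p = pm.generate_phantom(cfg, seed=0)
        res = pl.run_pipeline(p.mr, p.contours)
        brain = res.masks["brain"]
        outside = ~np.isin(
            p.truth.labels, [int(Label.BRAIN), int(Label.CSF), int(Label.CONTRAST)]
        )
        # a defect in the cranial vault must not let brain spill into scalp
        assert (brain & outside).sum() < 0.02 * brain.sum()
        assert dice_masks(brain, p.truth.labels == int(Label.BRAIN)) >= 0.9


def test_segmentation_scale_invariant_small():
    """The whole chain is relative to wmIntensity: rescaling changes nothing."""
    rng = np.random.default_rng(9)
    data = np.full((30, 30, 30), 0.0)
    data[5:25, 5:25, 5:25] = rng.normal(1000.0, 10.0, (20, 20, 20))
    body = np.zeros(data.shape, bool)
    body[5:25, 5:25, 5:25] = True
    r1 = find_wm_reference(mr(data), body)
    r2 = find_wm_reference(mr(data * 3.7), body)
    assert r1.wm_voxel == r2.wm_voxel
    assert r2.wm_intensity == pytest.approx(3.7 * r1.wm_intensity)
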