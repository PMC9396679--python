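import numpy as np
import pytest

from octapipe.angiography import (
    DEFAULT_SLABS,
    SlabSpec,
    build_angio_volume,
    enface_project,
    enhance_contrast,
    oct_fundus,
    speckle_variance,
)
from octapipe.phantom import generate_structural, species_preset
from octapipe.reconstruction import to_log_grayscale
from octapipe.volume_model import EnFaceImage, OCTVolume, SurfaceMap
from tests._oracles import rank_auc
from tests.conftest import small_meta


class TestSpeckleVariance:
    def test_identical_frames_give_exact_zero(self):
        frame = np.random.default_rng(0).random((32, 16))
        sv = speckle_variance(np.stack([frame] * 3))
        assert (sv == 0.0).all()

    def test_direct_formula(self):
        """Frames {0, 0.5, 1} at one voxel: sv = ((0.5)^2 * 2) / 3."""
        stack = np.zeros((3, 1, 1))
        stack[:, 0, 0] = [0.0, 0.5, 1.0]
        assert speckle_variance(stack)[0, 0] == pytest.approx(1 / 6)

    def test_additive_constant_invariance_and_quadratic_scaling(self):
        rng = np.random.default_rng(1)
        stack = rng.random((3, 20, 10))
        sv = speckle_variance(stack)
        np.testing.assert_allclose(speckle_variance(stack + 0.3), sv, atol=1e-12)
        np.testing.assert_allclose(speckle_variance(2.0 * stack), 4.0 * sv, rtol=1e-10)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            speckle_variance(np.zeros((1, 4, 4)))


@pytest.fixture(scope="module")
def angio_case():
    """Mouse phantom with vessels, its speckle-variance volume, and the
    truth in unjittered coordinates."""
    meta = small_meta(48)
    spec = species_preset(
        "mouse", meta=meta, seed=41, jitter_walk_sigma_px=0.0, n_vessels=6
    )
    vol, truth = generate_structural(spec)
    log = to_log_grayscale(vol)
    sv = build_angio_volume(log, register=False)
    return spec, truth, sv


class TestBuildAngioVolume:
    def test_shapes_and_determinism(self, angio_case):
        spec, truth, sv = angio_case
        assert sv.shape == (48, 512, 48)
        vol2, _ = generate_structural(spec)
        sv2 = build_angio_volume(to_log_grayscale(vol2), register=False)
        np.testing.assert_array_equal(sv, sv2)

    def test_vessels_discriminated_from_static_tissue(self, angio_case):
        """Speckle variance separates vessel from static tissue voxels
        with ROC AUC >= 0.9 at frame correlation 0.9."""
        _, truth, sv = angio_case
        z = np.arange(sv.shape[1])[None, :, None]
        tissue = (z >= truth.ilm_surface.z[:, None, :]) & (
            z < truth.rpe_surface.z[:, None, :] + 50
        )
        vm = truth.vessel_mask
        auc = rank_auc(sv[vm & tissue], sv[tissue & ~vm])
        assert auc >= 0.90

    def test_single_repeat_rejected(self):
        meta = small_meta(4, n_repeats=1, n_depth=64)
        vol = OCTVolume(
            data=np.zeros((4, 1, 64, 4)), meta=meta, intensity_domain="log_grayscale"
        )
        with pytest.raises(ValueError, match="N < 2"):
            build_angio_volume(vol)

    def test_auc_nondecreasing_in_frame_correlation(self):
        """Vessel/static separation improves with static frame
        correlation (AUC non-decreasing over {0.5, 0.7, 0.9}, tol 0.02)."""
        meta = small_meta(32)
        aucs = []
        for corr in (0.5, 0.7, 0.9):
            spec = species_preset(
                "mouse", meta=meta, seed=43, jitter_walk_sigma_px=0.0,
                static_frame_correlation=corr,
            )
            vol, truth = generate_structural(spec)
            sv = build_angio_volume(to_log_grayscale(vol), register=False)
            z = np.arange(sv.shape[1])[None, :, None]
            tissue = (z >= truth.ilm_surface.z[:, None, :]) & (
                z < truth.rpe_surface.z[:, None, :] + 50
            )
            vm = truth.vessel_mask
            aucs.append(rank_auc(sv[vm & tissue], sv[tissue & ~vm]))
        assert aucs[1] >= aucs[0] - 0.02
        assert aucs[2] >= aucs[1] - 0.02


class TestEnfaceProject:
    def _flat_surfaces(self, ny, nx, top, bot):
        return SurfaceMap(np.full((ny, nx), float(top))), SurfaceMap(
            np.full((ny, nx), float(bot))
        )

    def test_constant_slab_statistics(self):
        vol = np.full((4, 32, 5), 0.25)
        ilm, rpe = self._flat_surfaces(4, 5, 10, 18)
        slab = DEFAULT_SLABS["full"]
        assert (enface_project(vol, ilm, rpe, slab, "max").data == 0.25).all()
        assert (enface_project(vol, ilm, rpe, slab, "mean").data == 0.25).all()
        np.testing.assert_allclose(
            enface_project(vol, ilm, rpe, slab, "sum").data, 0.25 * 8
        )

    def test_max_dominates_mean_pointwise(self, angio_case):
        _, truth, sv = angio_case
        slab = DEFAULT_SLABS["full"]
        mx = enface_project(sv, truth.ilm_surface, truth.rpe_surface, slab, "max")
        mn = enface_project(sv, truth.ilm_surface, truth.rpe_surface, slab, "mean")
        assert (mx.data >= mn.data - 1e-12).all()

    def test_single_row_slab_returns_that_row(self):
        """Half-open [top, top+1) slab selects exactly row ``top``."""
        rng = np.random.default_rng(3)
        vol = rng.random((3, 20, 4))
        ilm, rpe = self._flat_surfaces(3, 4, 7, 15)
        slab = SlabSpec("one", "ILM", 0.0, 0.0, "ILM", 1.0, 0.0)
        out = enface_project(vol, ilm, rpe, slab, "mean")
        np.testing.assert_allclose(out.data, vol[:, 7, :])

    def test_empty_slab_rejected(self):
        vol = np.random.default_rng(0).random((3, 20, 4))
        ilm, rpe = self._flat_surfaces(3, 4, 30, 40)  # beyond depth range
        with pytest.raises(ValueError):
            enface_project(vol, ilm, rpe, DEFAULT_SLABS["full"], "max")

    def test_vessel_centerlines_light_up_superficial_slab(self, angio_case):
        """Truth vessel centrelines fall in the bright tail of the
        superficial/choroid en face angiograms."""
        from skimage.morphology import skeletonize

        _, truth, sv = angio_case
        z = np.arange(sv.shape[1])[None, :, None]
        in_slab = (z >= truth.ilm_surface.z[:, None, :]) & (
            z < truth.rpe_surface.z[:, None, :]
        )
        footprint = (truth.vessel_mask & in_slab).any(axis=1)
        centerline = skeletonize(footprint)
        img = enface_project(
            sv, truth.ilm_surface, truth.rpe_surface, DEFAULT_SLABS["full"], "max"
        )
        thr = np.percentile(img.data, 75)
        assert (img.data[centerline] > thr).mean() >= 0.8


class TestFundus:
    def test_equals_full_slab_sum_projection(self, mouse_bundle):
        vol = mouse_bundle["aligned"]
        fundus = oct_fundus(vol)
        raw = vol.data.sum(axis=1)
        rescaled = (raw - raw.min()) / (raw.max() - raw.min())
        np.testing.assert_allclose(fundus.data, rescaled, atol=1e-12)
        assert fundus.data.shape == (vol.meta.n_locations, vol.meta.n_ascans)

    def test_constant_volume_normalises_to_zero(self):
        meta = small_meta(3, n_repeats=1, n_depth=32)
        vol = OCTVolume(
            data=np.full((3, 32, 3), 0.5), meta=meta, is_averaged=True,
            intensity_domain="log_grayscale",
        )
        assert (oct_fundus(vol).data == 0.0).all()


class TestEnhanceContrast:
    def test_constant_image_maps_to_zero(self):
        img = EnFaceImage(np.full((16, 16), 0.4))
        out = enhance_contrast(img, 4.0, (1.0, 99.0))
        assert (out.data == 0.0).all()

    def test_removes_smooth_background_gradient(self):
        """Background subtraction + stretching raises correlation with
        the clean vessel pattern in the presence of an additive ramp."""
        rng = np.random.default_rng(9)
        clean = np.zeros((64, 64))
        clean[::8, :] = 1.0  # horizontal 'vessels'
        ramp = np.linspace(0, 2.0, 64)[:, None] * np.ones((1, 64))
        noisy = clean * 0.4 + ramp
        out = enhance_contrast(EnFaceImage(noisy), 10.0, (1.0, 99.0))
        r_before = np.corrcoef(noisy.ravel(), clean.ravel())[0, 1]
        r_after = np.corrcoef(out.data.ravel(), clean.ravel())[0, 1]
        assert r_after >= r_before
        assert out.data.min() >= 0.0 and out.data.max() <= 1.0

    def test_bad_percentiles_rejected(self):
        with pytest.raises(ValueError):
            enhance_contrast(EnFaceImage(np.zeros((4, 4))), 2.0, (90.0, 10.0))
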