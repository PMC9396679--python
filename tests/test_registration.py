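import numpy as np
import pytest
from scipy.ndimage import fourier_shift, gaussian_filter, laplace

from octapipe.phantom import generate_structural, species_preset
from octapipe.reconstruction import to_log_grayscale
from octapipe.registration import (
    apply_shift,
    average_bm_scans,
    average_bm_volume,
    axial_align_volume,
    estimate_shift_subpixel,
)
from tests._oracles import best_fractional_shift_1d, best_integer_shift
from tests.conftest import small_meta


@pytest.fixture(scope="module")
def textured():
    rng = np.random.default_rng(0)
    return gaussian_filter(rng.normal(size=(96, 80)), 2.0)


class TestEstimateShift:
    def test_identity(self, textured):
        assert estimate_shift_subpixel(textured, textured) == (0.0, 0.0)

    def test_integer_roll_recovered_exactly(self, textured):
        """Matches the exhaustive integer-shift correlation oracle."""
        mov = np.roll(textured, (3, -2), axis=(0, 1))
        est = estimate_shift_subpixel(textured, mov, upsample=1)
        oracle = best_integer_shift(textured, mov)
        assert est == (3.0, -2.0)
        assert oracle == (3, -2)

    def test_subpixel_shift_within_tenth_pixel(self, textured):
        """A 1.5 px Fourier shift is recovered to 0.1 px at upsample 10
        and agrees with a 0.05 px correlation-grid oracle."""
        mov = np.fft.ifft2(fourier_shift(np.fft.fft2(textured), (1.5, 0.0))).real
        dz, dx = estimate_shift_subpixel(textured, mov, upsample=10)
        assert 1.4 <= dz <= 1.6
        assert abs(dx) <= 0.1
        oracle = best_fractional_shift_1d(textured, mov)
        assert abs(oracle - 1.5) <= 0.051

    def test_antisymmetry(self, textured):
        mov = np.fft.ifft2(fourier_shift(np.fft.fft2(textured), (0.7, -1.2))).real
        f = estimate_shift_subpixel(textured, mov, upsample=10)
        b = estimate_shift_subpixel(mov, textured, upsample=10)
        assert f[0] == pytest.approx(-b[0], abs=0.1)
        assert f[1] == pytest.approx(-b[1], abs=0.1)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            estimate_shift_subpixel(np.ones((8, 8)), np.ones((8, 8)))


class TestApplyShift:
    def test_zero_shift_is_identity(self, textured):
        np.testing.assert_array_equal(apply_shift(textured, 0, 0), textured)

    def test_integer_shift_equals_roll(self, textured):
        np.testing.assert_allclose(
            apply_shift(textured, 2, 0), np.roll(textured, 2, axis=0), atol=1e-10
        )

    def test_integer_shift_inverse_to_1e10(self, textured):
        there = apply_shift(textured, 2, 0)
        back = apply_shift(there, -2, 0)
        np.testing.assert_allclose(back, textured, atol=1e-10)

    def test_fractional_shift_inverse_on_bandlimited_image(self):
        """Forward/backward fractional shifts cancel exactly for images
        with no Nyquist-frequency content (the Fourier-shift operator is
        unitary away from the Nyquist bin)."""
        rng = np.random.default_rng(4)
        F = np.fft.fft2(rng.normal(size=(64, 64)))
        fy = np.abs(np.fft.fftfreq(64))[:, None]
        fx = np.abs(np.fft.fftfreq(64))[None, :]
        F[(fy > 0.2) | (fx > 0.2)] = 0.0
        img = np.fft.ifft2(F).real
        back = apply_shift(apply_shift(img, 1.5, -0.5), -1.5, 0.5)
        np.testing.assert_allclose(back, img, atol=1e-10)

    def test_fractional_matches_upsampled_interpolation(self, textured):
        """1.5 px Fourier shift agrees with 10x zero-padded-FFT
        upsampling + integer shift + decimation (bandlimited image)."""
        shifted = apply_shift(textured, 1.5, 0.0)
        ny, nx = textured.shape
        up = 10
        F = np.fft.fftshift(np.fft.fft2(textured))
        big = np.zeros((ny * up, nx * up), complex)
        y0, x0 = (ny * up - ny) // 2, (nx * up - nx) // 2
        big[y0 : y0 + ny, x0 : x0 + nx] = F
        fine = np.fft.ifft2(np.fft.ifftshift(big)).real * up * up
        oracle = np.roll(fine, 15, axis=0)[::up, ::up]
        rms = np.sqrt(np.mean((shifted - oracle) ** 2))
        assert rms < 1e-3 * np.ptp(textured)


class TestAverageBM:
    def test_identical_frames_pass_through(self, textured):
        stack = np.stack([textured] * 3)
        avg, shifts = average_bm_scans(stack)
        np.testing.assert_allclose(avg, textured, atol=1e-12)
        assert shifts == [(0.0, 0.0)] * 3

    def test_three_repeats_give_one_frame(self, textured):
        stack = np.stack([textured] * 3)
        avg, _ = average_bm_scans(stack)
        assert avg.shape == textured.shape

    def test_registered_average_sharper_than_naive(self, textured):
        """With jittered frames, registration before averaging preserves
        sharpness (variance-of-Laplacian ratio > 1 vs naive mean)."""
        frames = [textured]
        for s in ((1.6, 0.0), (-1.2, 0.8)):
            frames.append(
                np.fft.ifft2(fourier_shift(np.fft.fft2(textured), s)).real
            )
        stack = np.stack(frames)
        registered, _ = average_bm_scans(stack, upsample=10)
        naive = stack.mean(axis=0)
        sharp = lambda im: laplace(im).var()  # noqa: E731
        assert sharp(registered) / sharp(naive) > 1.0

    def test_single_frame_passthrough(self, textured):
        avg, shifts = average_bm_scans(textured[None])
        np.testing.assert_array_equal(avg, textured)
        assert shifts == [(0.0, 0.0)]


class TestAxialAlign:
    @staticmethod
    def _tiled_volume(jitter=None, ny=40, seed=13):
        """Volume of one textured B-scan tiled to every location, each
        circularly rolled by a known per-location offset."""
        from octapipe.volume_model import OCTVolume

        meta = small_meta(ny, n_repeats=1, n_depth=256)
        meta.n_ascans = 32
        rng = np.random.default_rng(seed)
        bscan = np.clip(
            0.5 + gaussian_filter(rng.normal(0, 0.4, (256, 32)), 2.0), 0, 1
        )
        bscan[60:120] += 0.3  # a bright band dominating the axial profile
        bscan = np.clip(bscan, 0, 1)
        data = np.stack(
            [np.roll(bscan, 0 if jitter is None else int(jitter[y]), axis=0)
             for y in range(ny)]
        ).astype(np.float32)
        return OCTVolume(
            data=data, meta=meta, is_averaged=True,
            intensity_domain="log_grayscale",
        )

    def test_already_aligned_volume_gets_zero_offsets(self):
        vol = self._tiled_volume()
        _, offsets = axial_align_volume(vol)
        assert (offsets == 0).all()

    def test_reference_offset_is_zero(self):
        vol = self._tiled_volume()
        _, offsets = axial_align_volume(vol, ref_index=17)
        assert offsets[17] == 0

    def test_known_jitter_recovered_exactly_and_idempotent(self):
        """A known integer random walk is recovered exactly (relative to
        the reference) and a second pass is a no-op."""
        rng = np.random.default_rng(14)
        jitter = np.rint(np.cumsum(rng.normal(0, 2.0, 40))).astype(int)
        vol = self._tiled_volume(jitter=jitter)
        aligned, offsets = axial_align_volume(vol, ref_index=20)
        expected = -(jitter - jitter[20])
        np.testing.assert_array_equal(offsets, expected)
        _, second = axial_align_volume(aligned, ref_index=20)
        assert (second == 0).all()

    def test_phantom_jitter_recovered_within_one_px(self):
        """On a speckled layered phantom the recovered offsets match the
        injected random walk within +-1 px for nearly all locations."""
        meta = small_meta(120)
        spec = species_preset("mouse", meta=meta, seed=22, jitter_walk_sigma_px=2.0)
        vol, truth = generate_structural(spec)
        avg = average_bm_volume(to_log_grayscale(vol))
        _, offsets = axial_align_volume(avg, ref_index=60)
        expected = -(truth.jitter_px - truth.jitter_px[60])
        assert (np.abs(offsets - expected) <= 1).mean() >= 0.9

    def test_max_lag_bound(self):
        vol = self._tiled_volume()
        with pytest.raises(ValueError):
            axial_align_volume(vol, max_lag=vol.meta.n_depth // 2)

    def test_bm_form_rejected(self):
        meta = small_meta(4, n_repeats=2, n_depth=64)
        spec = species_preset("mouse", meta=meta, seed=1, jitter_walk_sigma_px=0.0,
                              ilm_center_depth_px=15.0, curvature_sag_px=2.0,
                              thickness_ripple_um=0.0,
                              layers=[("NFL", 20.0, 0.8), ("choroid", 20.0, 0.2)],
                              vessel_slab=("NFL",), n_vessels=0)
        vol, _ = generate_structural(spec)
        with pytest.raises(ValueError):
            axial_align_volume(to_log_grayscale(vol))
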