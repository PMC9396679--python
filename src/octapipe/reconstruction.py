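"""Spectral-fringe to depth-profile reconstruction.

The A-scan pipeline is fixed in order: reference-spectrum (DC)
subtraction, analytic-signal formation (one-sided spectrum), dispersion
compensation by a phase polynomial in normalised wavenumber, Hann
windowing, FFT, magnitude of the positive-depth half, logarithmic
compression, and affine grayscale mapping to [0, 1].

Fringes are assumed k-linear (hardware k-clock resampling); no software
resampler is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_model import FringeVolume, OCTVolume

__all__ = ["ReconParams", "reconstruct_ascan", "reconstruct_volume", "to_log_grayscale"]


@dataclass
class ReconParams:
    """Reconstruction parameters.

    ``dispersion_c2``/``dispersion_c3`` are the quadratic and cubic
    phase-polynomial coefficients (radians per normalised-k^2 / -k^3,
    with k centred and scaled to [-1, 1]).  ``dynamic_range_db`` is the
    (floor, ceil) window in dB mapped linearly onto the [0, 1]
    grayscale.  Depth magnitudes are normalised by n_k/2 so that a
    unit-amplitude spectral cosine reconstructs to unit reflectivity
    amplitude (0 dB); the default window (-30, +5) then matches the
    linear-intensity grayscale conversion and is a display choice, not
    a physical constant.
    """

    dispersion_c2: float = 0.0
    dispersion_c3: float = 0.0
    dynamic_range_db: tuple = (-30.0, 5.0)
    epsilon: float = 1e-12

    def __post_init__(self) -> None:
        floor, ceil = self.dynamic_range_db
        if not ceil > floor:
            raise ValueError("dynamic range ceiling must exceed floor")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


def _analytic(fringes: np.ndarray) -> np.ndarray:
    """Analytic signal along the last axis via the one-sided spectrum
    method (positive frequencies doubled, negative zeroed)."""
    n = fringes.shape[-1]
    spec = np.fft.fft(fringes, axis=-1)
    h = np.zeros(n)
    h[0] = 1.0
    h[1 : n // 2] = 2.0
    h[n // 2] = 1.0  # n is even (checked by callers)
    return np.fft.ifft(spec * h, axis=-1)


def _magnitude_profiles(fringes: np.ndarray, params: ReconParams) -> np.ndarray:
    """Linear-domain depth magnitude for fringes along the last axis
    (already reference-subtracted); output keeps the first n_k/2 bins."""
    n_k = fringes.shape[-1]
    kappa = np.linspace(-1.0, 1.0, n_k)
    analytic = _analytic(fringes)
    if params.dispersion_c2 != 0.0 or params.dispersion_c3 != 0.0:
        phase = params.dispersion_c2 * kappa**2 + params.dispersion_c3 * kappa**3
        analytic = analytic * np.exp(-1j * phase)
    window = np.hanning(n_k)
    spectrum = np.fft.fft(analytic * window, axis=-1)
    # n_k/2 = peak gain of a Hann-windowed unit-amplitude analytic cosine
    return np.abs(spectrum[..., : n_k // 2]) / (n_k / 2.0)


def _to_grayscale_db(mag: np.ndarray, params: ReconParams) -> np.ndarray:
    floor, ceil = params.dynamic_range_db
    db = 20.0 * np.log10(mag + params.epsilon)
    return np.clip((db - floor) / (ceil - floor), 0.0, 1.0)


def reconstruct_ascan(
    fringe: np.ndarray, params: ReconParams, reference: np.ndarray | None = None
) -> np.ndarray:
    """Reconstruct a single A-line to a grayscale depth profile.

    ``reference`` is the reference spectrum subtracted before the
    analytic-signal step; by default the fringe's own mean (scalar DC).
    Returns ``n_k/2`` grayscale values in [0, 1].
    """
    fringe = np.asarray(fringe, dtype=float)
    if fringe.ndim != 1:
        raise ValueError("reconstruct_ascan expects a 1-D fringe")
    n_k = fringe.shape[0]
    if n_k < 8 or n_k % 2:
        raise ValueError("fringe length must be even and >= 8")
    if not np.all(np.isfinite(fringe)):
        raise ValueError("fringe contains non-finite values")
    if reference is None:
        reference = np.full(n_k, fringe.mean())
    mag = _magnitude_profiles(fringe - reference, params)
    return _to_grayscale_db(mag, params)


def reconstruct_volume(fv: FringeVolume, params: ReconParams) -> OCTVolume:
    """Reconstruct a fringe volume to a BM-form log-grayscale volume.

    The reference spectrum subtracted from each frame is the mean fringe
    over the A-scans of that B-scan frame (per-frame DC/fixed-pattern
    estimate).  Output shape is (location, repeat, depth, ascan).
    """
    m = fv.meta
    if m.n_k == 0:
        raise ValueError(
            "volume is already reconstructed (n_k = 0); skip the reconstruction stage"
        )
    if m.n_k % 2:
        raise ValueError("n_k must be even")
    ny, nr = m.n_locations, m.n_repeats
    out = np.empty((ny, nr, m.n_depth, m.n_ascans), dtype=np.float32)
    for y in range(ny):
        frames = np.asarray(fv.data[y], dtype=float)  # (nr, nx, n_k)
        reference = frames.mean(axis=1, keepdims=True)  # per-frame mean fringe
        mag = _magnitude_profiles(frames - reference, params)  # (nr, nx, nz)
        out[y] = np.transpose(_to_grayscale_db(mag, params), (0, 2, 1))
    return OCTVolume(data=out, meta=m, is_averaged=False, intensity_domain="log_grayscale")


def to_log_grayscale(
    vol: OCTVolume, floor_db: float = -30.0, ceil_db: float = 5.0, epsilon: float = 1e-12
) -> OCTVolume:
    """Convert a linear-intensity volume to the log-grayscale domain.

    Applies ``10*log10(I + eps)`` (intensity dB, equivalent to 20*log10
    of amplitude) and maps [floor_db, ceil_db] onto [0, 1] with
    clipping.  The narrower default window than the fringe path reflects
    linear intensities being O(1) rather than FFT magnitudes.
    """
    if vol.intensity_domain != "linear":
        raise ValueError("volume is not in the linear intensity domain")
    if not ceil_db > floor_db:
        raise ValueError("ceil_db must exceed floor_db")
    db = 10.0 * np.log10(np.maximum(vol.data, 0.0) + epsilon)
    gray = np.clip((db - floor_db) / (ceil_db - floor_db), 0.0, 1.0)
    return OCTVolume(
        data=gray.astype(np.float32),
        meta=vol.meta,
        is_averaged=vol.is_averaged,
        intensity_domain="log_grayscale",
    )
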