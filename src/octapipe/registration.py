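"""Motion correction: sub-pixel BM-frame registration and axial
volume alignment.

Two motions are corrected, matching the two corrections applied during
acquisition post-processing: (1) translation between the repeated
B-scans of one location, estimated by FFT-based phase correlation with
local upsampled refinement and removed by Fourier-shift interpolation
before averaging; (2) axial (depth) offsets between neighbouring
averaged B-scans, estimated by integer-lag normalised cross-correlation
of their mean axial profiles and removed by circular rolls, propagated
outward from a reference B-scan.
"""

from __future__ import annotations

from typing import List, Tuple, Union

import numpy as np
from scipy.ndimage import fourier_shift
from skimage.registration import phase_cross_correlation

from .volume_model import OCTVolume

__all__ = [
    "estimate_shift_subpixel",
    "apply_shift",
    "average_bm_scans",
    "register_bm_stack",
    "average_bm_volume",
    "axial_align_volume",
]


def estimate_shift_subpixel(
    ref: np.ndarray, mov: np.ndarray, upsample: int = 10
) -> Tuple[float, float]:
    """Estimate the (dz, dx) displacement of ``mov`` relative to ``ref``.

    Returns the displacement such that ``mov ~ apply_shift(ref, dz, dx)``
    (i.e. for ``mov = np.roll(ref, (3, -2))`` the result is (3, -2)),
    with 1/``upsample`` pixel precision from upsampled cross-power-
    spectrum refinement around the integer correlation peak.
    """
    ref = np.asarray(ref, dtype=float)
    mov = np.asarray(mov, dtype=float)
    if ref.shape != mov.shape:
        raise ValueError("images must share a shape")
    if upsample < 1:
        raise ValueError("upsample must be >= 1")
    if np.ptp(ref) == 0 or np.ptp(mov) == 0:
        raise ValueError("phase correlation is undefined for constant images")
    shift, _, _ = phase_cross_correlation(ref, mov, upsample_factor=upsample)
    return (-float(shift[0]), -float(shift[1]))


def apply_shift(img: np.ndarray, dz: float, dx: float) -> np.ndarray:
    """Translate an image by (dz, dx) via the Fourier shift theorem.

    Integer shifts reproduce ``np.roll`` exactly (to floating round-off);
    fractional shifts interpolate with the periodic sinc kernel.
    """
    img = np.asarray(img, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    if dz == 0.0 and dx == 0.0:
        return img.copy()
    return np.fft.ifft2(fourier_shift(np.fft.fft2(img), (dz, dx))).real


def average_bm_scans(
    stack: np.ndarray, upsample: int = 10
) -> Tuple[np.ndarray, List[Tuple[float, float]]]:
    """Register the repeat frames of one location to frame 0 and average.

    Returns the averaged B-scan and the estimated per-frame
    displacements (frame 0 is the reference, (0.0, 0.0)).  A single
    frame passes through unchanged.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("expected a (repeat, depth, ascan) stack")
    shifts: List[Tuple[float, float]] = [(0.0, 0.0)]
    if stack.shape[0] == 1:
        return stack[0].copy(), shifts
    ref = stack[0]
    aligned = [ref]
    for i in range(1, stack.shape[0]):
        dz, dx = estimate_shift_subpixel(ref, stack[i], upsample=upsample)
        shifts.append((dz, dx))
        aligned.append(apply_shift(stack[i], -dz, -dx))
    return np.mean(aligned, axis=0), shifts


def register_bm_stack(
    stack: np.ndarray, upsample: int = 10
) -> Tuple[np.ndarray, List[Tuple[float, float]]]:
    """Register repeat frames to frame 0 without averaging (used by the
    angiography path, which needs the aligned stack itself)."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("expected a (repeat, depth, ascan) stack")
    out = np.empty_like(stack)
    out[0] = stack[0]
    shifts: List[Tuple[float, float]] = [(0.0, 0.0)]
    for i in range(1, stack.shape[0]):
        dz, dx = estimate_shift_subpixel(stack[0], stack[i], upsample=upsample)
        shifts.append((dz, dx))
        out[i] = apply_shift(stack[i], -dz, -dx)
    return out, shifts


def average_bm_volume(vol: OCTVolume, upsample: int = 10) -> OCTVolume:
    """Register-and-average the repeat frames of every location of a
    BM-form volume, returning the averaged volume."""
    if vol.is_averaged:
        raise ValueError("volume is already averaged")
    m = vol.meta
    out = np.empty((m.n_locations, m.n_depth, m.n_ascans), dtype=np.float32)
    for y in range(m.n_locations):
        avg, _ = average_bm_scans(vol.data[y], upsample=upsample)
        out[y] = avg
    if vol.intensity_domain == "log_grayscale":
        out = np.clip(out, 0.0, 1.0)
    return OCTVolume(
        data=out, meta=m, is_averaged=True, intensity_domain=vol.intensity_domain
    )


def _best_circular_lag(ref: np.ndarray, mov: np.ndarray, max_lag: int) -> int:
    """Integer lag l (|l| <= max_lag) maximising the circular NCC, with
    ``mov ~ np.roll(ref, l)``."""
    a = ref - ref.mean()
    b = mov - mov.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0
    corr = np.fft.ifft(np.fft.fft(b) * np.conj(np.fft.fft(a))).real / (na * nb)
    lags = np.concatenate([np.arange(0, max_lag + 1), np.arange(-max_lag, 0)])
    vals = np.concatenate([corr[: max_lag + 1], corr[-max_lag:]])
    return int(lags[np.argmax(vals)])


def axial_align_volume(
    vol: OCTVolume, ref_index: Union[int, str] = "auto", max_lag: int = 50
) -> Tuple[OCTVolume, np.ndarray]:
    """Correct inter-B-scan axial motion across an averaged volume.

    Each B-scan is collapsed to its mean axial profile; neighbouring
    profiles are registered by integer-lag normalised cross-correlation
    within ``+-max_lag`` and cumulative displacements are propagated
    outward from the reference B-scan in both directions.  Each B-scan
    is then circularly rolled by the returned per-location offset (the
    correction applied, i.e. approximately minus its displacement
    relative to the reference; ``offsets[ref_index] == 0``).

    ``ref_index='auto'`` picks the location of maximal total intensity
    as a deterministic proxy for a good-quality reference frame.
    """
    if not vol.is_averaged:
        raise ValueError("axial alignment expects an averaged volume")
    m = vol.meta
    if max_lag >= m.n_depth // 2:
        raise ValueError("max_lag must be < n_depth / 2")
    data = vol.data
    ny = m.n_locations
    if ref_index == "auto":
        ref_index = int(np.argmax(data.sum(axis=(1, 2))))
    ref_index = int(ref_index)
    if not 0 <= ref_index < ny:
        raise ValueError("ref_index out of range")

    profiles = data.mean(axis=2)  # (location, depth)
    disp = np.zeros(ny, dtype=int)  # displacement relative to reference
    for y in range(ref_index + 1, ny):
        disp[y] = disp[y - 1] + _best_circular_lag(
            profiles[y - 1], profiles[y], max_lag
        )
    for y in range(ref_index - 1, -1, -1):
        disp[y] = disp[y + 1] + _best_circular_lag(
            profiles[y + 1], profiles[y], max_lag
        )

    offsets = -disp
    out = np.empty_like(data)
    for y in range(ny):
        out[y] = np.roll(data[y], offsets[y], axis=0) if offsets[y] else data[y]
    aligned = OCTVolume(
        data=out, meta=m, is_averaged=True, intensity_domain=vol.intensity_domain
    )
    return aligned, offsets
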