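"""Retinal surface detection and B-scan flattening.

Per B-scan the top retinal surface is found by: Gaussian blur, 2-D
median filter, thresholding (to zero the noise above the surface), a
Canny edge map, taking the first edge row of each A-line scanning from
the vitreous side, median filtering of the resulting edge-row array to
reject outliers, and interpolation over A-lines without edges.  The
volume is then flattened by circularly shifting each A-line so its
detected surface lands on a pre-determined centre depth.  Circular
shifts preserve each A-line's voxel multiset exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.ndimage import gaussian_filter, median_filter
from skimage.feature import canny
from skimage.filters import threshold_otsu

from .volume_model import GENERIC_TOP, OCTVolume, SurfaceMap

__all__ = ["FlattenParams", "detect_surface_bscan", "flatten_volume", "applied_shifts"]


class SurfaceDetectionError(RuntimeError):
    """Raised when no edge is found anywhere in a B-scan."""


@dataclass
class FlattenParams:
    """Surface-detection and flattening parameters (all kernel sizes in
    pixels; odd kernels required).  ``center_depth_px=None`` defaults to
    ``n_depth // 3`` at flatten time."""

    gauss_sigma_px: float = 2.0
    median_kernel_px: int = 3
    threshold_method: str = "otsu"
    percentile_q: float = 75.0
    canny_sigma: float = 2.0
    canny_low: float = 0.1
    canny_high: float = 0.3
    surface_median_window: int = 15
    center_depth_px: int | None = None

    def __post_init__(self) -> None:
        if self.median_kernel_px % 2 == 0 or self.surface_median_window % 2 == 0:
            raise ValueError("median kernels must be odd")
        if self.threshold_method not in ("otsu", "percentile"):
            raise ValueError(f"unknown threshold method {self.threshold_method!r}")
        if not 0.0 < self.percentile_q < 100.0:
            raise ValueError("percentile_q must be in (0, 100)")
        if not self.canny_low < self.canny_high:
            raise ValueError("canny_low must be < canny_high")


def detect_surface_bscan(bscan: np.ndarray, params: FlattenParams) -> np.ndarray:
    """Detect the top (innermost) surface row per A-line of one B-scan.

    Returns a float array of length ``n_ascans``; columns where no edge
    was found are linearly interpolated from the nearest detected
    neighbours (edge columns extended constant).
    """
    bscan = np.asarray(bscan, dtype=float)
    if bscan.ndim != 2:
        raise ValueError("expected a 2-D (depth, ascan) B-scan")
    if not np.all(np.isfinite(bscan)):
        raise ValueError("B-scan contains non-finite values")
    nz, nx = bscan.shape

    smooth = gaussian_filter(bscan, params.gauss_sigma_px)
    smooth = median_filter(smooth, size=params.median_kernel_px)
    if params.threshold_method == "otsu":
        thr = threshold_otsu(smooth)
    else:
        thr = np.percentile(smooth, params.percentile_q)
    cleaned = np.where(smooth >= thr, smooth, 0.0)

    edges = canny(
        cleaned,
        sigma=params.canny_sigma,
        low_threshold=params.canny_low,
        high_threshold=params.canny_high,
        use_quantiles=False,
    )
    if not edges.any():
        raise SurfaceDetectionError("no edges detected in B-scan")

    # first nonzero edge row per column, scanning from depth 0 downward
    has_edge = edges.any(axis=0)
    first = np.argmax(edges, axis=0).astype(float)
    first[~has_edge] = np.nan

    # 1-D median over columns rejects isolated outliers; NaN-aware
    w = params.surface_median_window
    half = w // 2
    padded = np.pad(first, half, mode="edge")
    windows = np.lib.stride_tricks.sliding_window_view(padded, w)
    with np.errstate(all="ignore"):
        smoothed = np.nanmedian(windows, axis=1)
    smoothed[~has_edge] = np.nan

    # fill remaining gaps by linear interpolation between detections
    missing = np.isnan(smoothed)
    if missing.all():
        raise SurfaceDetectionError("no usable surface columns in B-scan")
    if missing.any():
        x = np.arange(nx)
        smoothed[missing] = np.interp(
            x[missing], x[~missing], smoothed[~missing]
        )
    return np.clip(smoothed, 0, nz - 1)


def applied_shifts(surface_z: np.ndarray, center_depth_px: int) -> np.ndarray:
    """Integer circular shift applied to each A-line during flattening:
    ``round(center - surface)``."""
    return np.rint(center_depth_px - np.asarray(surface_z, dtype=float)).astype(int)


def flatten_volume(
    vol: OCTVolume, params: FlattenParams | None = None
) -> Tuple[OCTVolume, SurfaceMap]:
    """Flatten an averaged volume to a common surface depth.

    Each A-line is circularly shifted by ``round(center_depth -
    detected_surface)`` so the detected top surface lands on the centre
    depth.  Returns the flattened volume and the pre-flattening surface
    map.  The voxel multiset of every A-line is preserved exactly.
    """
    if params is None:
        params = FlattenParams()
    if not vol.is_averaged:
        raise ValueError("flattening expects an averaged volume")
    m = vol.meta
    center = params.center_depth_px if params.center_depth_px is not None else m.n_depth // 3
    ny, nz, nx = vol.data.shape
    surface = np.empty((ny, nx), dtype=float)
    out = np.empty_like(vol.data)
    zz = np.arange(nz)[:, None]
    xx = np.arange(nx)[None, :]
    for y in range(ny):
        surface[y] = detect_surface_bscan(vol.data[y], params)
        shifts = applied_shifts(surface[y], center)
        # per-column circular roll: roll(a, s)[i] == a[(i - s) % n]
        out[y] = vol.data[y][(zz - shifts[None, :]) % nz, xx]
    flat = OCTVolume(
        data=out, meta=m, is_averaged=True, intensity_domain=vol.intensity_domain
    )
    return flat, SurfaceMap(z=surface, label=GENERIC_TOP)
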