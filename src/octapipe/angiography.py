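"""Speckle-variance OCT angiography and en face projections.

Flow contrast is the interframe intensity variance over the registered
repeat frames (BM-scans) of each location, computed on the log-grayscale
structural images with the population normalisation 1/N.  Vascular maps
are extracted as en face projections over anatomical slabs referenced to
the segmented ILM and RPE surfaces, and enhanced by background
subtraction plus percentile contrast stretching.  No projection-artifact
removal is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from . import registration
from .volume_model import EnFaceImage, OCTVolume, SurfaceMap

__all__ = [
    "SlabSpec",
    "speckle_variance",
    "build_angio_volume",
    "enface_project",
    "oct_fundus",
    "enhance_contrast",
    "default_slab",
    "DEFAULT_SLABS",
]


@dataclass
class SlabSpec:
    """Depth slab referenced to segmented surfaces.

    Offsets may be absolute pixels (``*_offset_px``) or fractions of the
    local retinal thickness (``*_offset_frac``); both are added to the
    reference surface.  The projection interval is half-open
    [top, bottom).
    """

    name: str = "full"
    top_ref: str = "ILM"
    top_offset_px: float = 0.0
    top_offset_frac: float = 0.0
    bottom_ref: str = "RPE"
    bottom_offset_px: float = 0.0
    bottom_offset_frac: float = 0.0

    def __post_init__(self) -> None:
        for ref in (self.top_ref, self.bottom_ref):
            if ref not in ("ILM", "RPE"):
                raise ValueError(f"slab reference must be ILM or RPE, got {ref!r}")

    def resolve(
        self, ilm: SurfaceMap, rpe: SurfaceMap
    ) -> Tuple[np.ndarray, np.ndarray]:
        """Per-column (top, bottom) fractional depths."""
        thickness = rpe.z - ilm.z
        refs = {"ILM": ilm.z, "RPE": rpe.z}
        top = refs[self.top_ref] + self.top_offset_px + self.top_offset_frac * thickness
        bot = (
            refs[self.bottom_ref]
            + self.bottom_offset_px
            + self.bottom_offset_frac * thickness
        )
        if not np.all(top < bot):
            raise ValueError(f"slab {self.name!r}: resolved top must lie above bottom")
        return top, bot


#: Anatomical slab presets: the superficial plexus in the NFL/GCL, the
#: intermediate plexus around the IPL, the deep plexus near INL/OPL
#: (percent-of-thickness bands adapt across species), and the choroid
#: below the RPE/BrM complex.
DEFAULT_SLABS = {
    "superficial": SlabSpec("superficial", "ILM", 0.0, 0.0, "ILM", 0.0, 0.25),
    "intermediate": SlabSpec("intermediate", "ILM", 0.0, 0.25, "ILM", 0.0, 0.55),
    "deep": SlabSpec("deep", "ILM", 0.0, 0.55, "RPE", 0.0, 0.0),
    "choroid": SlabSpec("choroid", "RPE", 0.0, 0.0, "RPE", 60.0, 0.0),
    "full": SlabSpec("full", "ILM", 0.0, 0.0, "RPE", 0.0, 0.0),
}


def default_slab(name: str) -> SlabSpec:
    if name not in DEFAULT_SLABS:
        raise ValueError(f"unknown slab {name!r}; known: {sorted(DEFAULT_SLABS)}")
    return DEFAULT_SLABS[name]


def speckle_variance(stack: np.ndarray) -> np.ndarray:
    """Interframe intensity variance of a registered repeat stack.

    ``sv(z, x) = (1/N) * sum_i (I_i - mean_i I)^2`` over the N >= 2
    repeats; computed on log-grayscale intensity.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("expected a (repeat, depth, ascan) stack")
    if stack.shape[0] < 2:
        raise ValueError("speckle variance needs at least 2 repeat frames")
    sv = stack.var(axis=0)
    # identical samples have exactly zero variance; guard the float
    # round-off of the mean subtraction
    sv[(stack == stack[0]).all(axis=0)] = 0.0
    return sv


def build_angio_volume(
    vol: OCTVolume,
    upsample: int = 10,
    axial_offsets: Optional[np.ndarray] = None,
    register: bool = True,
    despeckle_median: int = 3,
) -> np.ndarray:
    """Compute the speckle-variance volume of a BM-form volume.

    Per location the repeat frames are registered to the first frame
    (FFT subpixel registration) and their interframe variance taken.
    ``axial_offsets`` (per-location circular rolls, as returned by the
    structural axial alignment) are applied so segmentation surfaces
    from the structural pipeline line up with the angiogram.  The
    variance volume is then despeckled with a small 3-D median filter
    (``despeckle_median`` per side; 1 disables): single-voxel variance
    spikes arise wherever the shared speckle field has a near-null (the
    log transform amplifies frame-to-frame noise at low signal), while
    true flow voxels come in vessel-sized connected runs that survive
    the median.  Returns a (location, depth, ascan) array.
    """
    if vol.is_averaged:
        raise ValueError("angiography needs the BM-form (repeat-resolved) volume")
    m = vol.meta
    if m.n_repeats < 2:
        raise ValueError("speckle variance needs at least 2 repeat frames (N < 2)")
    ny = m.n_locations
    out = np.empty((ny, m.n_depth, m.n_ascans), dtype=np.float32)
    for y in range(ny):
        stack = vol.data[y]
        if register:
            stack, _ = registration.register_bm_stack(stack, upsample=upsample)
        out[y] = speckle_variance(stack)
        if axial_offsets is not None and axial_offsets[y]:
            out[y] = np.roll(out[y], int(axial_offsets[y]), axis=0)
    if despeckle_median > 1:
        from scipy.ndimage import median_filter

        out = median_filter(out, size=despeckle_median)
    return out


def enface_project(
    vol3d: np.ndarray,
    ilm: SurfaceMap,
    rpe: SurfaceMap,
    slab: SlabSpec,
    mode: str = "max",
) -> EnFaceImage:
    """Project a (location, depth, ascan) volume over a surface-referenced
    slab.

    Depth rows [ceil(top), ceil(bottom)) are reduced per column by the
    requested statistic; the interval is half-open and clipped to the
    volume's depth range (an entirely clipped slab is an error).
    """
    vol3d = np.asarray(vol3d)
    if vol3d.ndim != 3:
        raise ValueError("expected a (location, depth, ascan) volume")
    ny, nd, nx = vol3d.shape
    if ilm.z.shape != (ny, nx) or rpe.z.shape != (ny, nx):
        raise ValueError("surface maps must cover the projection grid")
    if mode not in ("max", "mean", "sum"):
        raise ValueError(f"unknown projection mode {mode!r}")
    top, bot = slab.resolve(ilm, rpe)
    top_i = np.clip(np.ceil(top).astype(int), 0, nd)
    bot_i = np.clip(np.ceil(bot).astype(int), 0, nd)
    if np.all(bot_i <= top_i):
        raise ValueError(f"slab {slab.name!r} is empty after clipping to the volume")

    # mask-based reduction over the half-open [top, bottom) interval
    z = np.arange(nd)[None, :, None]
    inside = (z >= top_i[:, None, :]) & (z < bot_i[:, None, :])
    counts = inside.sum(axis=1)
    counts_safe = np.maximum(counts, 1)
    if mode == "max":
        vals = np.where(inside, vol3d, -np.inf).max(axis=1)
        vals = np.where(counts > 0, vals, 0.0)
    elif mode == "sum":
        vals = np.where(inside, vol3d, 0.0).sum(axis=1)
    else:
        vals = np.where(inside, vol3d, 0.0).sum(axis=1) / counts_safe
    return EnFaceImage(data=vals, kind=f"angio_{mode}", slab=slab)


def oct_fundus(vol: OCTVolume) -> EnFaceImage:
    """Sum-projection fundus image of an averaged structural volume.

    Sums the full depth of every column and min-max normalises to
    [0, 1]; a constant (degenerate-range) projection maps to all zeros.
    """
    if not vol.is_averaged:
        raise ValueError("fundus projection expects an averaged volume")
    proj = vol.data.sum(axis=1)
    lo, hi = float(proj.min()), float(proj.max())
    if hi > lo:
        proj = (proj - lo) / (hi - lo)
    else:
        proj = np.zeros_like(proj)
    return EnFaceImage(data=proj, kind="fundus_sum")


def enhance_contrast(
    img: EnFaceImage,
    background_sigma_px: float = 20.0,
    stretch_percentiles: Tuple[float, float] = (1.0, 99.0),
) -> EnFaceImage:
    """Background subtraction plus percentile contrast stretching.

    Subtracts a large-kernel Gaussian background estimate, clips
    negatives, and linearly maps the [p_lo, p_hi] percentiles onto
    [0, 1] with clipping.  A degenerate percentile range yields an
    all-zero image.
    """
    p_lo, p_hi = stretch_percentiles
    if p_lo >= p_hi:
        raise ValueError("p_lo must be < p_hi")
    data = np.asarray(img.data, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("image contains non-finite values")
    flat = data - gaussian_filter(data, background_sigma_px)
    flat = np.maximum(flat, 0.0)
    lo, hi = np.percentile(flat, [p_lo, p_hi])
    if hi > lo:
        out = np.clip((flat - lo) / (hi - lo), 0.0, 1.0)
    else:
        out = np.zeros_like(flat)
    return EnFaceImage(data=out, kind=img.kind, slab=img.slab)
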