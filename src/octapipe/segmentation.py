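"""Graph-cut retinal layer segmentation and thickness statistics.

The inner limiting membrane / nerve fibre layer boundary (ILM/NFL) and
the retinal pigment epithelium / Bruch's membrane complex (RPE/BrM) are
each found as the globally optimal surface of a column cost volume:
the surface z(y, x) minimising the summed per-column cost subject to
hard smoothness constraints |dz| <= smooth_dx (resp. smooth_dy) between
laterally (resp. azimuthally) adjacent columns.  The minimiser is
computed exactly as a minimum s-t cut on the standard optimal-surface
(minimum closure) graph: one node per voxel, infinite intra-column arcs
pointing up, infinite inter-column arcs encoding the smoothness bound,
and node weights given by the axial cost differences.

Costs are signed axial gradients of the Gaussian-smoothed volume:
the ILM is the strongest dark-to-bright transition, the RPE/BrM the
strongest bright-to-dark transition at least ``min_separation_px``
below the ILM (a sequential two-pass search).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from ._maxflow import S_TREE, bk_maxflow, build_csr
from .volume_model import ILM_NFL, RPE_BRM, OCTVolume, SurfaceMap

__all__ = [
    "GraphCutParams",
    "ThicknessResult",
    "solve_optimal_surface",
    "segment_surfaces_graphcut",
    "compute_thickness",
]

_INT_SCALE = 2**12  # fixed-point scale for float costs


@dataclass
class GraphCutParams:
    """Graph-cut segmentation parameters.

    ``smooth_dx_px`` / ``smooth_dy_px`` bound the surface height change
    between adjacent A-scans within a B-scan / between adjacent B-scans;
    setting one >= n_depth removes that coupling.  ``search_band_*``
    optionally restricts each surface to a depth window (zmin, zmax),
    half-open; on flattened volumes the ILM sits near the flattening
    centre depth, so a narrow band is both principled and fast.
    ``refine_subpixel`` enables parabolic interpolation of the cost
    around the integer optimum (default off: keeps the exact-optimality
    contract testable).
    """

    smooth_dx_px: int = 2
    smooth_dy_px: int = 2
    min_separation_px: int = 20
    cost_sigma_px: float = 2.0
    cost_lateral_sigma_px: float = 1.0
    search_band_ilm: Optional[Tuple[int, int]] = None
    search_band_rpe: Optional[Tuple[int, int]] = None
    refine_subpixel: bool = False

    def __post_init__(self) -> None:
        if self.smooth_dx_px < 0 or self.smooth_dy_px < 0:
            raise ValueError("smoothness bounds must be >= 0")
        if self.min_separation_px < 1:
            raise ValueError("min_separation_px must be >= 1")


@dataclass
class ThicknessResult:
    """Retinal thickness map and summary statistics (micrometres)."""

    thickness_um: np.ndarray
    mean_um: float
    sd_um: float
    n_columns: int
    mask: Optional[np.ndarray] = None


def _integer_costs(cost: np.ndarray) -> np.ndarray:
    """Fixed-point cost volume; integer inputs pass through unchanged so
    optimality can be compared exactly against integer oracles."""
    cost = np.asarray(cost)
    if np.issubdtype(cost.dtype, np.integer):
        return cost.astype(np.int64)
    peak = np.abs(cost).max()
    if peak == 0:
        return np.zeros(cost.shape, dtype=np.int64)
    return np.rint(cost * (_INT_SCALE / peak)).astype(np.int64)


def solve_optimal_surface(
    cost: np.ndarray, smooth_dx: int, smooth_dy: int
) -> np.ndarray:
    """Exact minimiser of ``sum_col cost[y, x, z(y, x)]`` under the hard
    smoothness constraints, via minimum s-t cut.

    ``cost`` is (n_bscans, n_ascans, n_depth); float costs are converted
    to fixed point (integer costs are used as-is).  Returns the integer
    surface z[y, x].
    """
    cost = np.asarray(cost)
    if cost.ndim != 3:
        raise ValueError("cost volume must be 3-D (y, x, z)")
    ny, nx, nd = cost.shape
    if nd < 1:
        raise ValueError("empty depth range")
    ci = _integer_costs(cost)

    # node weights: telescoping axial differences; the per-column base
    # node (z = 0) is forced into the closure through a huge excess
    w = ci.copy()
    w[:, :, 1:] = ci[:, :, 1:] - ci[:, :, :-1]
    ids = np.arange(ny * nx * nd, dtype=np.int32).reshape(ny, nx, nd)
    INF = np.int64(2) ** 52

    tails = []
    heads = []

    def _add(t, h):
        # arcs in reverse pairs: (t->h, INF), (h->t, 0)
        tails.append(np.stack([t, h], axis=1).ravel())
        heads.append(np.stack([h, t], axis=1).ravel())

    # intra-column: (z) -> (z - 1)
    _add(ids[:, :, 1:].ravel(), ids[:, :, :-1].ravel())

    # inter-column smoothness arcs (z) -> (neighbour, z - delta); arcs
    # into z' <= 0 are redundant (the base is always closed) and skipped
    for axis, delta in ((1, smooth_dx), (0, smooth_dy)):
        if delta >= nd:
            continue
        zt = np.arange(nd) - delta
        keep = zt >= 1
        if not keep.any():
            continue
        ztk = zt[keep]
        for sign in (1, -1):
            if axis == 1:
                src = ids[:, 1:, :][:, :, keep] if sign > 0 else ids[:, :-1, :][:, :, keep]
                dst = ids[:, :-1, :][:, :, ztk] if sign > 0 else ids[:, 1:, :][:, :, ztk]
            else:
                src = ids[1:, :, :][:, :, keep] if sign > 0 else ids[:-1, :, :][:, :, keep]
                dst = ids[:-1, :, :][:, :, ztk] if sign > 0 else ids[1:, :, :][:, :, ztk]
            _add(src.ravel(), dst.ravel())

    excess = (-w).ravel().astype(np.int64)
    big = np.abs(w).sum() + 1
    excess[ids[:, :, 0].ravel().astype(np.int64)] += big

    tails = np.concatenate(tails)
    heads = np.concatenate(heads)
    caps = np.zeros(tails.size, dtype=np.int64)
    caps[0::2] = INF  # forward structural arcs; reverses stay 0
    first, head, rev, cap = build_csr(tails, heads, caps, ny * nx * nd)
    _, tree = bk_maxflow(first, head, rev, cap, excess)
    closed = (tree == S_TREE).reshape(ny, nx, nd)
    # topmost... deepest closed node per column is the surface position
    z = nd - 1 - np.argmax(closed[:, :, ::-1], axis=2)
    return z.astype(np.int64)


def _axial_gradient(
    vol_data: np.ndarray, sigma: float, lateral_sigma: float
) -> np.ndarray:
    """Axial derivative of the Gaussian-smoothed volume, as (y, x, z).

    Lateral smoothing is kept much weaker than axial: surfaces are
    tilted by curvature, and lateral blur washes out the axial edges of
    the deeper (more tilted) boundaries."""
    smooth = gaussian_filter(
        np.asarray(vol_data, dtype=float), (lateral_sigma, sigma, lateral_sigma)
    )
    grad = np.gradient(smooth, axis=1)  # depth axis of (y, z, x)
    return np.transpose(grad, (0, 2, 1))


def _parabolic_refine(cost: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Sub-pixel surface via a parabola through the cost at z-1, z, z+1."""
    ny, nx, nd = cost.shape
    zc = np.clip(z, 1, nd - 2)
    yy, xx = np.mgrid[0:ny, 0:nx]
    c0 = cost[yy, xx, zc - 1]
    c1 = cost[yy, xx, zc]
    c2 = cost[yy, xx, zc + 1]
    denom = c0 - 2.0 * c1 + c2
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(np.abs(denom) > 1e-12, 0.5 * (c0 - c2) / denom, 0.0)
    frac = np.clip(frac, -0.5, 0.5)
    out = z.astype(float)
    interior = (z >= 1) & (z <= nd - 2)
    out[interior] += frac[interior]
    return out


def segment_surfaces_graphcut(
    vol: OCTVolume, params: GraphCutParams | None = None
) -> Tuple[SurfaceMap, SurfaceMap]:
    """Segment the ILM/NFL and RPE/BrM surfaces of a flattened volume.

    Sequential two-pass search: the ILM minimises the negated
    dark-to-bright axial gradient cost; the RPE/BrM minimises the
    negated bright-to-dark gradient cost over depths at least
    ``min_separation_px`` below the found ILM.  Both passes are exact
    graph-cut minimisers; the returned surfaces satisfy
    ``ilm.z + min_separation_px <= rpe.z`` everywhere.
    """
    if params is None:
        params = GraphCutParams()
    if not vol.is_averaged:
        raise ValueError("segmentation expects an averaged (flattened) volume")
    nd = vol.meta.n_depth
    grad = _axial_gradient(
        vol.data, params.cost_sigma_px, params.cost_lateral_sigma_px
    )  # (y, x, z)

    def _band(band, default):
        zmin, zmax = band if band is not None else default
        zmin, zmax = int(zmin), int(zmax)
        if not 0 <= zmin < zmax <= nd:
            raise ValueError(f"search band ({zmin}, {zmax}) invalid for depth {nd}")
        return zmin, zmax

    ilm_lo, ilm_hi = _band(params.search_band_ilm, (0, nd))
    ilm_cost_f = -grad[:, :, ilm_lo:ilm_hi]
    ilm_cost = _integer_costs(ilm_cost_f)
    ilm_z = (
        solve_optimal_surface(ilm_cost, params.smooth_dx_px, params.smooth_dy_px)
        + ilm_lo
    )

    rpe_lo, rpe_hi = _band(params.search_band_rpe, (0, nd))
    min_rpe = ilm_z + params.min_separation_px
    if rpe_hi <= int(min_rpe.min()):
        raise ValueError("RPE search band lies entirely above ILM + min separation")
    rpe_cost_f = grad[:, :, rpe_lo:rpe_hi]
    rpe_cost = _integer_costs(rpe_cost_f)
    # forbid depths above ILM + min_separation with a prohibitive cost;
    # the bound surface itself is feasible (it inherits the ILM's
    # smoothness), so the optimum never pays the penalty
    z_rel = np.arange(rpe_lo, rpe_hi)[None, None, :]
    forbidden = z_rel < min_rpe[:, :, None]
    # exceeds the largest possible cost difference between two surfaces
    # (per-column fixed-point costs are bounded by _INT_SCALE)
    penalty = np.int64(2) * _INT_SCALE * min_rpe.size + 1
    rpe_cost = np.where(forbidden, penalty, rpe_cost)
    rpe_z = (
        solve_optimal_surface(rpe_cost, params.smooth_dx_px, params.smooth_dy_px)
        + rpe_lo
    )
    rpe_z = np.maximum(rpe_z, min_rpe)  # safety net; no-op when feasible

    if params.refine_subpixel:
        ilm_out = _parabolic_refine(-grad, ilm_z)
        rpe_out = _parabolic_refine(grad, rpe_z)
    else:
        ilm_out = ilm_z.astype(float)
        rpe_out = rpe_z.astype(float)
    return SurfaceMap(z=ilm_out, label=ILM_NFL), SurfaceMap(z=rpe_out, label=RPE_BRM)


def compute_thickness(
    ilm: SurfaceMap,
    rpe: SurfaceMap,
    axial_um_per_px: float,
    mask: Optional[np.ndarray] = None,
) -> ThicknessResult:
    """Retinal thickness map and mean +- SD over unmasked columns.

    ``mask`` marks columns to *exclude*.  The SD is the population
    standard deviation.  Crossing surfaces in unmasked columns are an
    error.
    """
    if ilm.z.shape != rpe.z.shape:
        raise ValueError("surfaces must share a shape")
    if axial_um_per_px <= 0:
        raise ValueError("axial_um_per_px must be > 0")
    thickness = (rpe.z - ilm.z) * axial_um_per_px
    if mask is None:
        mask = np.zeros(thickness.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != thickness.shape:
            raise ValueError("mask must match the surface shape")
    valid = ~mask
    if not valid.any():
        raise ValueError("all columns are masked")
    if np.any(thickness[valid] <= 0):
        raise ValueError("crossing or touching surfaces in unmasked columns")
    vals = thickness[valid]
    return ThicknessResult(
        thickness_um=thickness,
        mean_um=float(vals.mean()),
        sd_um=float(vals.std()),
        n_columns=int(valid.sum()),
        mask=mask,
    )
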