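"""Synthetic retinal phantom generator.

Emulates a swept-source OCT raster acquisition of a layered retina:
ordered reflectivity bands (NFL ... RPE, then choroid) draped over a
parabolic dome, fully developed multiplicative speckle, repeat-frame
decorrelation inside vessels (flow contrast), per-location axial motion
as an integer random walk, and optional sub-pixel repeat-frame shifts.
Every generated volume comes with its complete ground truth so each
downstream processing stage can be validated without real data.

The speckle model is the standard coherent-imaging statistic: intensity
in a uniform region is exponentially distributed with unit mean, applied
multiplicatively to the layer reflectivity.  Repeat frames of one
location share a common speckle field blended with per-frame independent
fields at weight ``1 - static_frame_correlation`` for static tissue,
while vessel voxels redraw their speckle independently every repeat
(intensity decorrelation is the contrast mechanism of speckle-variance
angiography; no Doppler phase is modelled).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .volume_model import (
    ILM_NFL,
    RPE_BRM,
    AcquisitionMeta,
    FringeVolume,
    OCTVolume,
    SurfaceMap,
)

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "generate_structural",
    "synthesize_fringes",
    "species_preset",
    "SPECIES_THICKNESS_UM",
    "SPECIES_OCULAR_PARAMS",
]

#: Published in vivo retinal thickness (mean, SD) in micrometres per species.
SPECIES_THICKNESS_UM: Dict[str, Tuple[float, float]] = {
    "mouse": (210.0, 10.0),
    "rat": (186.0, 15.0),
    "owl": (260.0, 24.0),
    "opossum": (138.5, 14.0),
    "sturgeon": (142.0, 12.0),
}

#: Representative ocular parameters per species (pupil mm, NA_max, focal
#: length mm, optical power D, axial length mm) — preset metadata only.
SPECIES_OCULAR_PARAMS: Dict[str, Dict[str, float]] = {
    "mouse": dict(pupil_mm=2.0, na_max=0.49, focal_mm=1.9, power_d=520, axial_mm=3.3),
    "rat": dict(pupil_mm=3.0, na_max=0.43, focal_mm=3.3, power_d=300, axial_mm=6.1),
    "owl": dict(pupil_mm=13.3, na_max=0.38, focal_mm=17.2, power_d=58, axial_mm=28.5),
    "opossum": dict(pupil_mm=6.0, na_max=0.44, focal_mm=5.1, power_d=196, axial_mm=10.0),
    "sturgeon": dict(pupil_mm=2.1, na_max=0.44, focal_mm=1.9, power_d=532, axial_mm=3.6),
}

# Relative reflectivity of the retinal bands, inner to outer.  Bright
# NFL and OPL over dark nuclear layers, a bright photoreceptor/RPE
# complex, and a moderately scattering choroid below — the ordering seen
# in rodent B-scans.  The RPE->choroid drop is the strongest
# bright->dark transition so the outer boundary is well defined.
_DEFAULT_RETINAL_LAYERS: List[Tuple[str, float]] = [
    ("NFL", 0.85),
    ("GCL", 0.30),
    ("IPL", 0.60),
    ("INL", 0.25),
    ("OPL", 0.50),
    ("ONL", 0.20),
    ("ISOS", 0.70),
    ("RPE", 0.95),
]
_CHOROID_REFLECTIVITY = 0.22
_CHOROID_THICKNESS_UM = 100.0
_SCLERA_REFLECTIVITY = 0.12
_SCLERA_THICKNESS_UM = 250.0


def _default_layers(total_retina_um: float) -> List[Tuple[str, float, float]]:
    """Equal-proportion retinal bands scaled to a total ILM->RPE distance,
    plus choroid and sclera bands below.  Per-layer fractions are a
    declared default, not a biological claim."""
    per = total_retina_um / len(_DEFAULT_RETINAL_LAYERS)
    layers = [(name, per, refl) for name, refl in _DEFAULT_RETINAL_LAYERS]
    layers.append(("choroid", _CHOROID_THICKNESS_UM, _CHOROID_REFLECTIVITY))
    layers.append(("sclera", _SCLERA_THICKNESS_UM, _SCLERA_REFLECTIVITY))
    return layers


@dataclass
class PhantomSpec:
    """Full description of a synthetic acquisition.

    ``layers`` is the ordered (name, thickness_um, mean_reflectivity)
    stack from NFL to choroid; the last layer named ``choroid`` lies
    below the RPE/BrM boundary.  ``curvature_sag_px`` is the
    centre-to-corner sag of the parabolic dome all surfaces follow.
    ``thickness_ripple_um`` adds a smooth sinusoidal retina-thickness
    modulation of that amplitude (ground-truth thickness SD equals half
    the amplitude), so recovered thickness statistics have a nonzero
    truth to be compared against.  ``jitter_walk_sigma_px`` is the step
    SD of the per-location axial random walk; ``bm_jitter_px`` optionally
    adds uniform sub-pixel axial shifts to repeat frames 1..R-1.
    """

    meta: AcquisitionMeta = field(default_factory=AcquisitionMeta)
    layers: List[Tuple[str, float, float]] = field(
        default_factory=lambda: _default_layers(210.0)
    )
    ilm_center_depth_px: Optional[float] = None  # default: n_depth / 3
    curvature_sag_px: float = 20.0
    thickness_ripple_um: float = 20.0
    speckle_contrast: float = 1.0
    static_frame_correlation: float = 0.9
    n_vessels: int = 12
    vessel_radius_px: float = 3.0
    vessel_slab: Tuple[str, ...] = ("NFL", "OPL", "choroid")
    jitter_walk_sigma_px: float = 2.0
    bm_jitter_px: float = 0.0
    noise_floor: float = 0.005
    attenuation_per_px: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ilm_center_depth_px is None:
            self.ilm_center_depth_px = self.meta.n_depth / 3.0
        if not self.layers:
            raise ValueError("layer stack is empty")
        for name, t_um, refl in self.layers:
            if t_um <= 0:
                raise ValueError(f"layer {name!r} thickness must be > 0")
            if not 0.0 <= refl <= 1.0:
                raise ValueError(f"layer {name!r} reflectivity outside [0, 1]")
        if not 0.0 <= self.speckle_contrast <= 1.0:
            raise ValueError("speckle_contrast outside [0, 1]")
        if not 0.0 <= self.static_frame_correlation <= 1.0:
            raise ValueError("static_frame_correlation outside [0, 1]")
        if self.curvature_sag_px < 0:
            raise ValueError("curvature_sag_px must be >= 0")
        total_px = self.total_stack_px + self.curvature_sag_px
        if self.ilm_center_depth_px + total_px >= self.meta.n_depth:
            raise ValueError(
                "layer stack plus sag does not fit below the ILM centre depth "
                f"({self.ilm_center_depth_px} + {total_px:.1f} >= {self.meta.n_depth})"
            )
        names = [n for n, _, _ in self.layers]
        for slab_name in self.vessel_slab:
            if slab_name not in names:
                raise ValueError(f"vessel slab layer {slab_name!r} not in layer stack")

    @property
    def layer_names(self) -> List[str]:
        return [n for n, _, _ in self.layers]

    @property
    def n_retinal_layers(self) -> int:
        """Number of layers above the choroid (the retina proper)."""
        names = self.layer_names
        return names.index("choroid") if "choroid" in names else len(names)

    @property
    def retina_thickness_um(self) -> float:
        """Nominal ILM->RPE distance (all layers above the choroid)."""
        return sum(t for _, t, _ in self.layers[: self.n_retinal_layers])

    @property
    def total_stack_px(self) -> float:
        return sum(t for _, t, _ in self.layers) / self.meta.axial_um_per_px


@dataclass
class PhantomTruth:
    """Ground truth of a generated phantom.

    Surfaces are in motion-free coordinates (before the axial jitter is
    applied); ``jitter_px`` holds the per-location integer offsets the
    volume was rolled by.
    """

    ilm_surface: SurfaceMap
    rpe_surface: SurfaceMap
    thickness_um: np.ndarray
    vessel_mask: np.ndarray
    jitter_px: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if not np.all(self.ilm_surface.z < self.rpe_surface.z):
            raise ValueError("truth ILM must lie above truth RPE everywhere")


def _truth_surfaces(spec: PhantomSpec):
    """Fractional boundary depths b[i][y, x] for every layer interface,
    i = 0 (ILM) .. n_layers (bottom of choroid)."""
    m = spec.meta
    ny, nx = m.n_locations, m.n_ascans
    yy = np.linspace(-1.0, 1.0, ny)[:, None]
    xx = np.linspace(-1.0, 1.0, nx)[None, :]
    dome = spec.curvature_sag_px * (yy**2 + xx**2) / 2.0
    ilm = spec.ilm_center_depth_px + dome

    t0 = spec.retina_thickness_um
    # one full sine cycle per axis: gentle slopes, exactly zero mean over
    # the grid, and spatial SD equal to half the amplitude
    ripple = spec.thickness_ripple_um * np.sin(
        2.0 * np.pi * np.arange(ny)[:, None] / ny
    ) * np.sin(2.0 * np.pi * np.arange(nx)[None, :] / nx)
    scale = 1.0 + ripple / t0  # relative per-column retinal thickness

    boundaries = [ilm]
    z = ilm.copy()
    n_ret = spec.n_retinal_layers
    for i, (_, t_um, _) in enumerate(spec.layers):
        t_px = t_um / m.axial_um_per_px
        # the thickness ripple modulates the retina proper only
        z = z + (t_px * scale if i < n_ret else t_px)
        boundaries.append(z.copy())
    return boundaries


def _vessel_mask(spec: PhantomSpec, boundaries, rng: np.random.Generator) -> np.ndarray:
    """Boolean (location, depth, ascan) mask of vessel voxels: straight
    tubes of the configured radius, alternating along-x / along-y, hosted
    in the named layers (cycled per vessel) and following the surface
    curvature."""
    m = spec.meta
    ny, nz, nx = m.n_locations, m.n_depth, m.n_ascans
    mask = np.zeros((ny, nz, nx), dtype=bool)
    if spec.n_vessels == 0:
        return mask
    names = spec.layer_names
    r = spec.vessel_radius_px
    z_idx = np.arange(nz)
    for i in range(spec.n_vessels):
        host = spec.vessel_slab[i % len(spec.vessel_slab)]
        li = names.index(host)
        frac = rng.uniform(0.25, 0.75)
        along_x = i % 2 == 0
        if along_x:
            y0 = int(rng.integers(0, ny))
            centre = boundaries[li][y0, :] + frac * (
                boundaries[li + 1][y0, :] - boundaries[li][y0, :]
            )  # (nx,)
            ys = np.arange(max(0, int(y0 - r)), min(ny, int(y0 + r) + 1))
            dy2 = (ys - y0)[:, None, None] ** 2
            dz2 = (z_idx[None, :, None] - centre[None, None, :]) ** 2
            mask[ys] |= dy2 + dz2 <= r * r
        else:
            x0 = int(rng.integers(0, nx))
            centre = boundaries[li][:, x0] + frac * (
                boundaries[li + 1][:, x0] - boundaries[li][:, x0]
            )  # (ny,)
            xs = np.arange(max(0, int(x0 - r)), min(nx, int(x0 + r) + 1))
            dx2 = (xs - x0)[None, None, :] ** 2
            dz2 = (z_idx[None, :, None] - centre[:, None, None]) ** 2
            mask[:, :, xs] |= dx2 + dz2 <= r * r
    return mask


def _reflectivity_volume(spec: PhantomSpec, boundaries) -> np.ndarray:
    """Noise-free mean-intensity map (location, depth, ascan): layer
    reflectivity between its boundaries attenuated with depth below the
    ILM (single-scattering light loss), plus the additive noise floor.
    A voxel at integer depth d belongs to layer i when b[i] <= d < b[i+1];
    deep layers thereby fade smoothly into the floor as in real B-scans."""
    m = spec.meta
    ny, nz, nx = m.n_locations, m.n_depth, m.n_ascans
    refl = np.zeros((ny, nz, nx), dtype=np.float32)
    z = np.arange(nz)[None, :, None]
    for i, (_, _, rho) in enumerate(spec.layers):
        top = boundaries[i][:, None, :]
        bot = boundaries[i + 1][:, None, :]
        refl[(z >= top) & (z < bot)] = rho
    if spec.attenuation_per_px > 0:
        depth_below = z - boundaries[0][:, None, :]
        att = np.exp(
            -spec.attenuation_per_px * np.maximum(depth_below, 0.0)
        ).astype(np.float32)
        refl *= att
    return refl + np.float32(spec.noise_floor)


def generate_structural(spec: PhantomSpec) -> Tuple[OCTVolume, PhantomTruth]:
    """Generate a BM-form linear-intensity volume plus ground truth.

    Deterministic given ``spec.seed``.  Mean intensity inside each layer
    is proportional to its configured reflectivity; repeat frames of a
    location share that location's axial jitter offset (jitter models
    inter-B-scan motion).
    """
    m = spec.meta
    rng = np.random.default_rng(spec.seed)
    ny, nr, nz, nx = m.n_locations, m.n_repeats, m.n_depth, m.n_ascans

    boundaries = _truth_surfaces(spec)
    ilm_z = boundaries[0]
    names = spec.layer_names
    n_retina = names.index("choroid") if "choroid" in names else len(names)
    rpe_z = boundaries[n_retina]

    vessels = _vessel_mask(spec, boundaries, rng)
    base = _reflectivity_volume(spec, boundaries)

    c = spec.static_frame_correlation
    sc = spec.speckle_contrast
    shared = rng.exponential(1.0, size=(ny, nz, nx)).astype(np.float32)
    out = np.empty((ny, nr, nz, nx), dtype=np.float32)
    n_vessel_vox = int(vessels.sum())
    for r in range(nr):
        indep = rng.exponential(1.0, size=(ny, nz, nx)).astype(np.float32)
        speckle = c * shared + (1.0 - c) * indep
        if n_vessel_vox:
            speckle[vessels] = rng.exponential(1.0, size=n_vessel_vox).astype(
                np.float32
            )
        mult = 1.0 + sc * (speckle - 1.0)
        out[:, r] = base * mult

    # inter-B-scan axial motion: integer random walk shared by all
    # repeats of a location, applied as a circular roll in depth
    if spec.jitter_walk_sigma_px > 0:
        steps = rng.normal(0.0, spec.jitter_walk_sigma_px, size=ny)
        jitter = np.rint(np.cumsum(steps)).astype(int)
    else:
        jitter = np.zeros(ny, dtype=int)
    for y in range(ny):
        if jitter[y]:
            out[y] = np.roll(out[y], jitter[y], axis=1)

    # optional sub-pixel repeat-frame shifts (exercises BM registration)
    if spec.bm_jitter_px > 0:
        from scipy.ndimage import fourier_shift

        for y in range(ny):
            for r in range(1, nr):
                dz = rng.uniform(-spec.bm_jitter_px, spec.bm_jitter_px)
                frame = out[y, r]
                shifted = np.fft.ifft2(
                    fourier_shift(np.fft.fft2(frame), (dz, 0.0))
                ).real
                out[y, r] = np.maximum(shifted, 0.0)

    vol = OCTVolume(data=out, meta=m, is_averaged=False, intensity_domain="linear")
    truth = PhantomTruth(
        ilm_surface=SurfaceMap(z=ilm_z, label=ILM_NFL),
        rpe_surface=SurfaceMap(z=rpe_z, label=RPE_BRM),
        thickness_um=(rpe_z - ilm_z) * m.axial_um_per_px,
        vessel_mask=vessels,
        jitter_px=jitter,
        seed=spec.seed,
    )
    return vol, truth


def synthesize_fringes(
    structural: OCTVolume, spec: PhantomSpec, dc_level: float = 1.0
) -> FringeVolume:
    """Turn a linear-intensity volume into k-linear spectral fringes.

    Each A-line's fringe is a DC term plus
    ``sum_z sqrt(I(z)) * cos(2*pi*z*k/n_k + phi_z)`` with per-voxel
    phases ``phi_z`` drawn once per volume (seeded from ``spec.seed``),
    evaluated with an inverse FFT.  Fourier reconstruction of the result
    recovers the depth profile up to windowing blur.
    """
    if structural.intensity_domain != "linear":
        raise ValueError("fringe synthesis needs a linear-intensity volume")
    m = structural.meta
    if m.n_k != 2 * m.n_depth:
        raise ValueError(f"n_k ({m.n_k}) must equal 2 * n_depth ({m.n_depth})")
    n_k = m.n_k
    data = structural.data
    if structural.is_averaged:
        data = data[:, None]
    ny, nr = data.shape[0], data.shape[1]

    phase_rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0x0F]))
    phases = phase_rng.uniform(0.0, 2.0 * np.pi, size=(ny, m.n_depth, m.n_ascans))

    out = np.empty((ny, nr, m.n_ascans, n_k), dtype=np.float32)
    for y in range(ny):
        amp = np.sqrt(np.maximum(data[y], 0.0))  # (nr, nz, nx)
        coeff = amp * np.exp(1j * phases[y])[None]  # (nr, nz, nx)
        spectrum = np.zeros((nr, m.n_ascans, n_k), dtype=np.complex128)
        spectrum[:, :, : m.n_depth] = np.transpose(coeff, (0, 2, 1))
        fringe = n_k * np.fft.ifft(spectrum, axis=-1).real + dc_level
        out[y] = fringe.astype(np.float32)
    return FringeVolume(data=out, meta=m)


def species_preset(name: str, **overrides) -> PhantomSpec:
    """Phantom preset for one of the imaged species.

    Retinal layer thicknesses are equal-proportion defaults scaled so
    the total ILM->RPE distance equals the species' published mean, and
    the thickness ripple amplitude is twice the published SD (so the
    ground-truth map reproduces mean and SD exactly).  The owl preset
    places vessels only in the choroid: the avian retina is avascular,
    overlying a highly vascularised choroid.
    """
    key = name.lower()
    if key not in SPECIES_THICKNESS_UM:
        raise ValueError(
            f"unknown species {name!r}; known: {sorted(SPECIES_THICKNESS_UM)}"
        )
    mean_um, sd_um = SPECIES_THICKNESS_UM[key]
    kwargs: dict = dict(
        layers=_default_layers(mean_um),
        thickness_ripple_um=2.0 * sd_um,
        seed=0,
    )
    if key == "owl":
        kwargs["n_vessels"] = 8
        kwargs["vessel_slab"] = ("choroid",)
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)
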