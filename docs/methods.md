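# Methods

This note documents the models, algorithms and numerical choices behind
`octapipe`, what the synthetic phantom does and does not emulate, and
the problem sizes used by the test suite and the acceptance script.

## Acquisition model

The data model mirrors a raster-scanned swept-source retinal system:
`n_locations` slow-axis B-scan positions, `n_repeats` repeated B-scans
(BM-scans) per position, `n_ascans` A-scans per B-scan, and `n_k`
spectral samples per A-scan reconstructed to `n_depth = n_k/2` depth
pixels. The defaults — 360 locations × 3 repeats × 360 A-scans,
2048 → 1024 depth pixels, 100 kHz sweep rate, 1060 nm centre
wavelength, ~100 nm tuning range, ~50° field — reproduce the geometry
of such a system; 360·3·360 A-scans at 100 kHz give a 3.9 s raster,
i.e. the familiar "volume in four seconds" figure.

The axial sampling pitch is derived from the source: the imaging depth
of a swept-source system is `λ₀²·n_k / (8·n·Δλ)`; with λ₀ = 1.06 µm,
Δλ = 0.1 µm, n_k = 2048 and tissue index n ≈ 1.38 this is ≈ 2.1 mm over
1024 pixels, so the default `axial_um_per_px` is 2.0 µm (in tissue).
It is a metadata field, not a hard-coded constant.

## Reconstruction

The A-line pipeline is fixed in order: (1) reference-spectrum
subtraction — per frame, the mean fringe over that frame's A-scans,
which removes DC and common-mode fixed pattern while tolerating slow
source drift; (2) analytic signal by the one-sided-spectrum method;
(3) dispersion compensation by multiplying `exp(−i(c₂κ² + c₃κ³))`
with κ the centred normalised wavenumber in [−1, 1]; (4) Hann window;
(5) FFT, keeping the magnitude of the first n_k/2 bins; (6) log
compression and affine mapping of a dB window onto [0, 1].

Depth magnitudes are normalised by n_k/2, the peak gain of a
Hann-windowed unit-amplitude analytic cosine. A spectral cosine of
amplitude √I therefore reconstructs to amplitude √I — 0 dB for unit
reflectivity — which makes the fringe path dimensionally consistent
with the direct linear-intensity grayscale conversion
(`10·log₁₀ I`, window (−30, +5) dB by default). Without this
normalisation the FFT gain of ≈ +54 dB (n_k = 2048) pushes the noise
floor to mid-gray and crushes all sub-unity reflectivities into the top
of the display range. The dB window is a display choice and is
CLI-overridable; dispersion coefficients default to zero (the phantom's
k-clock fringes are undispersed).

Reconstruction is exact up to windowing blur: the Hann window couples
each depth bin with its two neighbours (3-tap kernel in the depth
domain), so with independent per-voxel phases the recovered intensity
is a locally mixed version of the input. Consistency tests therefore
compare intensities after a σ = 2 px axial Gaussian on both sides
(measured Pearson r ≈ 0.92 on a noiseless phantom; unsmoothed per-voxel
r is bounded near 0.78 by this mixing, not by an implementation error).

## Registration

Two motions are corrected, matching the two corrections a BM-scan
protocol needs. Interframe (within-location) translation is estimated
by FFT phase correlation with local upsampled cross-power refinement
(scikit-image's implementation of the standard algorithm; default
precision 0.1 px) and removed by Fourier-shift interpolation before
averaging. Inter-B-scan axial motion is estimated on the 1-D mean
axial profile of each averaged B-scan — integer-lag normalised
cross-correlation against its neighbour within ±`max_lag` (default
50 px) — and cumulative offsets are propagated outward from a reference
B-scan, chosen automatically as the location with maximal total
intensity (a deterministic proxy for "a good-quality central frame";
overridable). Corrections are circular rolls, consistent with the
flattening stage. The 1-D collapse is robust to lateral content change
between neighbouring B-scans; its known limitation is that genuine
smooth anatomical depth drift is indistinguishable from motion, which
is harmless here because flattening re-references every A-line.

Fractional Fourier shifts of images with energy at the Nyquist
frequency are not exactly invertible (the Nyquist bin's phase factor
breaks Hermitian symmetry and the real projection loses it); integer
shifts reproduce `np.roll` to 1e-10.

## Flattening

Per B-scan: Gaussian blur (σ = 2 px), 3×3 median, Otsu thresholding to
zero sub-threshold pixels (mainly the vitreous above the surface),
Canny edges (σ = 2, relative thresholds 0.1/0.3), first edge row per
A-line scanning from the vitreous side, a 1-D median (window 15) over
the edge-row array to reject outliers, and linear interpolation over
columns with no edge. The volume is flattened by circular per-A-line
shifts of `round(center_depth − surface)`; the centre depth defaults to
`n_depth/3`. Circular shifts preserve each A-line's voxel multiset
exactly; all thresholds and kernels are parameters.

At strongly reduced lateral sampling the dome is steeper per column and
the surface median window biases the detected surface near the fastest
slopes; tests that assert tight truth agreement therefore use gentle
sag or noiseless phantoms, while the flattening quality criterion
(post-flatten surface SD < 1.5 px at 40 px sag) is evaluated under full
speckle.

## Graph-cut segmentation

Each boundary is the exact global minimiser of
`Σ_columns cost(y, x, z(y, x))` subject to hard smoothness constraints
`|Δz| ≤ smooth_dx` between A-scan neighbours and `≤ smooth_dy` between
B-scan neighbours. The minimiser is computed as a minimum s-t cut on
the standard optimal-surface (minimum-closure) graph: one node per
voxel in the search band, infinite upward intra-column arcs, infinite
inter-column arcs from (c, z) to (neighbour, z − Δ), node weights given
by telescoping axial cost differences, and per-column base nodes forced
into the closure. Costs are the axial derivative of the
Gaussian-smoothed volume — negated for the ILM/NFL (dark→bright) and
as-is for the RPE/BrM (bright→dark). Axial smoothing σ = 2 px; lateral
smoothing is deliberately weaker (σ = 1 px) because surfaces are tilted
by curvature and heavy lateral blur selectively erodes the axial edges
of the deeper, more tilted boundaries.

The two surfaces are found sequentially: the RPE pass forbids depths
above `ilm + min_separation` (default 20 px) via a prohibitive cost
that exceeds any achievable cost difference; since the shifted ILM
itself satisfies the smoothness constraints, a feasible surface always
exists and the optimum never pays the penalty. Float costs are
converted to fixed point at 2¹² per unit max amplitude; integer costs
pass through unchanged so optimality can be verified exactly against an
independent per-B-scan dynamic-programming oracle (they must agree
whenever `smooth_dy ≥ n_depth` decouples the B-scans — tested, and
exact in 20/20 random volumes). At a discrete step edge the smoothed
gradient extremum straddles the two boundary voxels; ties resolve to
the minimal closure (the shallower surface), a half-pixel convention
that cancels in thickness.

The max-flow solver is an in-package Boykov–Kolmogorov implementation
(numba-compiled, terminal capacities folded into per-node excesses).
`scipy.sparse.csgraph.maximum_flow` was measured at ~7 s for a 144k-node
surface graph and ~68 s at 720k nodes — far too slow for volume-scale
use — while the BK tree-search algorithm is the standard choice for
vision grid graphs; it solves a 180×180×64 band in ~4–9 s. Correctness
is property-tested against scipy's flow values on random graphs. BK's
runtime degrades when the cost volume is noise-dominated (near-i.i.d.
costs are its pathological case), which is why cost smoothing matters
operationally as well as statistically.

Search bands are parameters; on flattened volumes the detected surface
sits at the centre depth by construction, so the pipeline defaults to
an ILM band of ±40 px around the centre and an RPE band of 800 µm below
it — both anatomy-scale bounds, not tuned values. Optional parabolic
sub-pixel refinement of the cut position exists but defaults off to
keep the optimiser's exactness testable.

Thickness is `(z_RPE − z_ILM)·axial_um_per_px`, reported as arithmetic
mean ± population SD over unmasked columns.

## Speckle-variance angiography

Flow contrast is the interframe variance `sv = (1/N)·Σ(Iᵢ − Ī)²` over
the N registered repeats, computed on the log-grayscale intensity
(variance on log intensity is insensitive to local brightness, unlike
linear-domain variance, which scales with I² and would rank bright
static tissue above dim choroidal vessels). Identical frames give
exactly zero (guarded against float round-off of the mean).

Log-domain variance has a known failure mode: wherever the shared
speckle field has a near-null, the relative frame-to-frame fluctuation
of the small residual signal is large and the log transform turns it
into an isolated variance spike in static tissue. These spikes are
single-voxel and spatially uncorrelated, whereas true flow fills
vessel-diameter runs; a 3×3×3 median filter on the variance volume —
standard angiogram despeckling — removes them (measured: vessel/static
ROC AUC 0.81 → 0.94 at frame correlation 0.5; the avascular-owl
retina-to-choroid 99th-percentile ratio 0.60 → 0.05). The filter size
is a parameter (1 disables).

En face maps are half-open [top, bottom) projections over slabs
referenced to the segmented surfaces. Default slabs: superficial
[ILM, ILM + 25 % thickness), intermediate [+25 %, +55 %), deep
[+55 %, RPE), choroid [RPE, RPE + 60 px ≈ 120 µm). Percent-of-thickness
slabs adapt across species; the named plexus anatomy is qualitative, so
the numeric boundaries are declared defaults. Retinal slabs project by
maximum intensity, the choroid by mean; the structural fundus image is
the full-depth sum, min–max normalised (a constant projection maps to
zero). Contrast enhancement subtracts a large-σ Gaussian background and
stretches the [p1, p99] percentiles onto [0, 1]. No projection-artifact
removal is applied anywhere.

## The phantom

The generator emulates, with ground truth: (1) ordered reflectivity
bands NFL … RPE over choroid and sclera, draped on a parabolic dome
(centre-to-corner sag) with a one-cycle sinusoidal retina-thickness
modulation whose amplitude is twice the target SD (so the truth map's
mean and SD are exact by construction; species presets use the
published in vivo means and SDs — mouse 210 ± 10 µm, rat 186 ± 15, owl
260 ± 24, opossum 138.5 ± 14, sturgeon 142 ± 12 — with equal-proportion
layer fractions, a declared default, not a biological claim);
(2) fully developed speckle: unit-mean exponential intensity applied
multiplicatively, with `speckle_contrast` blending toward the
deterministic mean; (3) repeat-frame correlation: static voxels blend a
shared field with per-frame fields at weight 1 − c, vessel voxels
redraw independently every frame (intensity decorrelation only — no
Doppler phase, matching an intensity-based angiography method);
(4) depth attenuation `exp(−µ(z − z_ILM))` with µ = 0.01 px⁻¹, so deep
bands fade smoothly into the additive noise floor as in real B-scans
(without it the synthetic sclera/background edge is the strongest
bright→dark transition in the volume and segmentation locks onto an
artefact); (5) axial bulk motion as a per-location integer random walk
applied as circular rolls shared by all repeats, plus optional
sub-pixel repeat-frame shifts; (6) straight vessel tubes (alternating
along-x/along-y) hosted in named layers — NFL, OPL and choroid by
default; choroid-only for the owl preset, whose retina is avascular.
Fringe synthesis assigns each voxel a fixed uniform random phase and
builds `DC + Σ_z √I(z)·cos(2πzk/n_k + φ_z)` by inverse FFT.

Not emulated: optical PSF/aberrations, sensitivity roll-off, fringe
washout, Doppler phase, projection shadowing of vessels, pecten or
hyaloid geometry, eye-specific optics (the per-species ocular
parameters are carried as preset metadata only). Passing tests
demonstrate the pipeline's correctness under this model — speckle
statistics, motion, decorrelation and layered geometry — not
performance on any real retina.

## Problem sizes

Tests and the acceptance script run reduced rasters chosen so the suite
completes quickly while every stage still operates well above its
noise floor: 1080-frame geometry checks at full metadata scale;
reconstruction oracles at n_k = 128–2048; axial-jitter recovery on a
180-location, 180-A-scan, 512-depth phantom (the criterion scale);
flattening at 60×3×60×512 with 40 px sag; segmentation recovery on
90×3×90×512 phantoms (ten seeded phantoms across the mouse, owl and
opossum presets in the test suite; two seeds per species in the
acceptance script) with graph bands of 50/200 depth pixels; angiography
at 40–48 lateral positions. A full 360×3×360×1024 volume is supported
by the same code paths but sized for workstation use.

## Known limitations

- The axial NCC alignment absorbs smooth anatomical depth drift into
  its motion estimate (mitigated by flattening).
- Graph-cut runtime and memory grow linearly in band depth × columns;
  unbanded full-depth volumes at full raster scale are impractical on a
  laptop-class machine.
- The two surfaces are found sequentially, not as a coupled
  two-surface graph; `min_separation` is the only inter-surface
  constraint.
- Sub-pixel surface refinement is off by default; integer surfaces
  quantise thickness at one pixel (2 µm at the default scale).
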