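# Methods

This note documents the models, the numerical choices, and what the
synthetic-data generators do and do not emulate. Parameter defaults are
given with units; everything listed is exposed in the corresponding config
or function signature.

## Coordinate and unit conventions

Image coordinates are 0-based, pixel-center, with x = column and y = row,
everywhere in the package. Times are minutes for single-cell kinetics and
hours for growth; lengths are pixels at the analysis level and are
converted by a user-supplied scale (µm/px for light microscopy, nm/px for
TEM — the scale comes from the instrument or scale bar; the package never
reads scale bars).

## Two-phase trace model

A valve-formation trace rises exponentially, F(t) = F0·e^(k·t), until
t_peak, where it attains its maximum F1. Cells with a decay phase
(fraction 0.75 by default, reflecting the observed cell-to-cell
variability) then decline monotonically to a floor F2 = decay_floor·F1
(default 0.5) which they reach at t_peak + t_dec and hold. The decay is
an exponential segment *normalised to attain the floor at its end*:

    F(t_peak + τ) = F2 + (F1 − F2)·(e^(−rτ) − e^(−rT))/(1 − e^(−rT)),  τ ≤ T,

with T = t_dec and curvature r (default 1.5/t_dec). The functional form
of the decay is not constrained by the observations the generator
emulates; we chose a form with a defined minimum because measured traces
show a clear landmark F2 (a kink), not an asymptote — an asymptotic decay
would make the duration of the decay phase a property of the recording
length rather than of the cell, and no estimator could time it. With
r·T = 1.5 the decline still has visibly nonzero slope at the minimum.
Cells without a decay keep accumulating, so segmentation reports their
decay phase as undefined.

Defaults for the population: k = 0.013 min⁻¹ and t_Exp = 90 min
(the observed population means at the growth-optimal pHe), t_Dec = 47 min,
5-min frame interval, all exposed in `TimelapseConfig`.

## Time-lapse generator

Cells are uniform disks (radius 6 px by default) whose *integrated*
intensity at each frame equals the closed-form trace exactly before noise;
a uniform disk rather than a Gaussian spot gives the sharp photometric
boundary that level-line extraction assumes. The scene adds a constant
background (default 100), an optional planar gradient, uniform drift
(bulk medium flow), per-frame Gaussian jitter, and i.i.d. additive
Gaussian read noise. Identical (config, seed) pairs are bit-identical.
Not emulated: the optical PSF, photobleaching, Poisson photon statistics,
3-D structure, and bright-field contrast — so passing tests demonstrate
correct photometry and tracking under drift and read noise, not robustness
to optical blur or shot noise.

Noise levels are stated as per-pixel SNR at trace peak. Because
photometry integrates over n ≈ πr² ≈ 113 pixels, the integrated-trace
noise is peak/(SNR·√n) (`trace_noise_sigma`); trace-level studies use this
equivalence rather than re-rendering images.

## Imaging stage

*Denoising* is patch-based non-local means (patch 5, search distance 6,
h = 0.8·σ̂) with a total-variation (Chambolle) alternative behind the same
contract; both preserve the frame mean to well under 1%.

*Detection* thresholds with Otsu, but only trusts the threshold when it
clears the background median by 3 robust standard deviations — Otsu
bisects even a pure-noise histogram, and an empty frame must yield an
empty detection list. Regions within the area bounds contribute an
intensity-weighted centroid; strongly elongated regions (axis ratio > 2)
are flagged as possible touching cells.

*Tracking* is greedy nearest-neighbour linking per frame pair, after
subtracting the median displacement of tentative matches (the bulk flow),
gated at a configurable radius (default 10 px). Greedy assignment by
ascending residual distance resolves crossings by minimal total
displacement. Tracks shorter than ⌈45 min / frame interval⌉ + 1
observations are dropped, mirroring the kinetic inclusion rule.

*Local background* is the median of an annulus (1.5–3× the expected cell
radius) excluding detected-cell pixels, falling back (flagged) to the
frame-wide median when fewer than 10 annulus pixels survive.

*Level-line shape extraction* enumerates iso-intensity contours at 256
evenly spaced levels (1/256 of the windowed dynamic range) of a lightly
smoothed copy of the frame (Gaussian σ = 0.6 px — a finite-difference
gradient on a hard pixelated edge is otherwise unstable). Contrast is the
mean bilinearly interpolated gradient magnitude along the contour. Every
level crossing a sharp edge produces near-maximal contrast, so instead of
a bare argmax (whose position within the edge band is decided by
pixelation noise) the selection keeps all enclosing contours within 95%
of the best contrast and returns the one at the band's median level,
centring the boundary on the edge; ties within one level go to the
smaller area. A(L) is the shoelace area of the contour polygon; W(L) is
the minimum over orientations of the width of a band containing L,
computed by rotating calipers over the contour's convex hull (the minimal
band is attained parallel to a hull edge). On binary disks and rectangles
this recovers areas within ~1% and widths within ~0.5 px.

The biovolume of a tracked cell is V = A(L)·W(L): a centric cell lying on
its girdle in a shallow capillary has a depth along the optical axis close
to its in-plane width. By default the pipeline extracts the shape once
per track, at the brightest observation, and re-centres the boundary
polygon at each frame's detection centroid: the cell's size is constant
over a run, photometry is linear in the aperture, and per-frame
re-extraction (available via `shape_per_frame`) costs ~100× more for no
measurable change in the fitted k.

## Kinetics stage

Intensity→concentration uses an OLS dilution line (the 9-level, 0–62.5 µM
design of the emulated calibration);
concentration = ((signal − intercept)/slope)/biovolume, clipped at zero,
with samples outside the fitted domain flagged as extrapolated.

Phase segmentation smooths with a centred 3-sample moving median, then
takes the first local maximum with prominence ≥ 10% of the smoothed range
*and* height ≥ 50% of the smoothed maximum — the accumulation maximum is
the brightest point of the trace, and the height guard rejects noise bumps
on the rise that prominence alone admits. The peak index is then refined
to the raw-series argmax within the smoothing half-window, because a
median filter skews plateau peaks by one sample. F2 is the minimum after
F1 and before any re-increase; when a decay exists its endpoint is
re-estimated by least-squares fitting of the kneed-exponential decay
(floor, rate and knee time free; F1 pinned to the peak sample), which
localises the knee well below the sampling interval. The fit falls back
to the nonparametric landmark when it fails or the knee runs off the
record. Non-decreasing traces report no decay phase.

The exponential phase is fitted in log space — ln F regressed on t — so k
is the slope, F0 = e^intercept, and the fit quality is the Pearson
correlation |r| of ln F vs t, which is the natural statistic for the
log-linear form. Acceptance requires r > 0.95 and ≥ 45 min of data before
F1. Both rules are logged per excluded cell with a reason code so the
population filtering is auditable.

Traces that never reach a maximum within the record (cells without a
decay phase, or track fragments caught mid-rise) carry no F1 landmark:
their phase amplitudes F1−F0 and F1−F2 are reported as undefined rather
than computed from the record's last sample, which would measure the
recording length instead of the cell. The rate k remains defined and
reportable for such cells — the log-slope needs no peak.

pH responses are fitted as y = a·e^(b·pHe) by log-linear regression on
the *level means* within a restricted domain (default pHe 6.4–8.2; the
most basic treatment departs from the exponential trend and is excluded
from these fits).

## SDV dye-partitioning model

The reporter is a monoprotic weak base: its neutral form crosses
membranes freely, its protonated form does not. At equilibrium the total
mobile dye in the SDV relative to outside is

    E = (1 + 10^(pKa − pH_SDV)) / (1 + 10^(pKa − pH_out)),

F_free is the neutral form (equal inside and out) and F_bound the
protonated excess. The dye's pKa is not published; the default is 7.5
(configurable). Entrapment in silica is irreversible with flux
κ·F_bound·V (κ default 0.01 min⁻¹), so the fixed amount A = F_fixed·V is
non-decreasing — the no-dissolution assumption. SDV pH enters as a
piecewise-linear trajectory and volume as exponential or logistic growth
(the expansion is known only to be non-linear). The mobile pool is at
instantaneous equilibrium; A is integrated by a fixed-step midpoint rule
on the user's grid, with a stability guard (κ·Δt ≤ 0.5). Conservation
F_total = F_free + F_bound + F_fixed holds to 10⁻⁹ relative by
construction and is asserted per step. In the protonation-dominated
regime (pH ≪ pKa) an SDV pH shift of ΔpH changes the accumulated
concentration 10^ΔpH-fold, which is how measured fold-changes are read as
intra-SDV pH shifts (~13.8-fold ↔ ~1.1 units). The model is a minimal
formalisation: the source analysis states the three-fraction sum and the
qualitative dynamics, not the rate law.

## Valve generator and morphometry

The valve generator places dark disks on a perturbed triangular lattice
(spacing 24 px, radius 5 px, jitter and radius-CV configurable), grouped
into fingers of 3 rows separated by bright ribs; the configured rib width
is the pore-edge-to-pore-edge gap, which is what the rib-width measurement
d2 estimates. Because the number of rows and columns that fit in a frame
is quantized, the analytic radius for a target porosity lands within a few
percent; when a target porosity is requested the radii are rescaled after
placement so the realized interior porosity matches it exactly. Additive
Gaussian noise emulates detector noise; electron-optical contrast
mechanisms are not modelled.

Morphometry binarizes with Otsu plus a 1-px opening, guarded by a
class-separation test (4 pooled standard deviations) so pore-free images
yield empty masks. Pores are connected components with equivalent-circle
radius R = √(A/π) within bounds, circularity 4πA/P² ≥ 0.6 (Crofton
perimeter), border-touching components excluded. Adjacency is the
Delaunay triangulation; d1 statistics use only edges whose two endpoints
have bounded, in-image Voronoi cells, since truncated cells bias spacing.
Fingers are single-linkage clusters cut at 1.4× the median
nearest-neighbour distance (the within-finger pitch; Delaunay-edge medians
would be contaminated by cross-rib edges in strongly anisotropic
layouts). Each finger's principal axis comes from the SVD of its centered
pore coordinates; D is the pore extent (centers ± R) perpendicular to the
finger's own axis, and d2 the gap between adjacent finger extents along
the sign-aligned mean perpendicular direction. A single finger reports d2
as undefined.

Porosity is ΣπR² over the pores whose centers lie in an interior window
(inset by 2× the largest radius by default) divided by the window area.
Attributing whole pore areas to the window by center position is unbiased
for a homogeneous pore field and avoids the downward bias of discarding
border pores while keeping the full image area. Macro traits (valve
width, fultoportulae, rimoportulae) come from supplied annotations —
cp is the minimum pairwise fultoportula distance, rp the mean consecutive
rimoportula distance ordered by angle around their centroid; automatic
detection of these structures is out of scope and missing annotations
yield NaN columns, never errors.

## Physiology

Growth is fitted as ln(density) vs time by OLS (µ = slope, doubling time
ln 2/µ; non-growing cultures are flagged with infinite doubling time).
Quotas are unit bookkeeping: µM in the extract × extract volume / cells,
reported in pmol cell⁻¹; the incorporation rate is BSi quota / µ and
diverges (flagged) as µ → 0. The molybdenum-blue chemistry itself is out
of scope; its standard curve enters as externally supplied slope and
intercept. The BCECF calibration fits a four-parameter logistic in pH
(increasing; analytic inverse) and falls back to an OLS line when the
sigmoid is unidentifiable on the sampled range — no plateaus sampled
(fitted dynamic range > 5× the observed span), midpoint far outside the
domain, or an implausibly steep hill term. Non-monotone level means
beyond a 5% tolerance are an error, since a calibration must be
invertible. Out-of-range ratios are clamped to the achievable range and
mapped to the domain edge.

## Acceptance script problem sizes

`scripts/acceptance.py` uses: 5 valve images per porosity level and 20
for the recovery regression (384² px); 12 cells over two ratiometric
image pairs per pHi span; 500 kinetic traces at per-pixel SNR 10 plus 200
pure-noise traces; 100 level-line phantoms (96² px); a six-pH cohort of
10 cells × 44 frames (224² px) per level, with k following
1.1×10⁻³·e^(0.32·pHe) and the exponential-phase amplitude law e^(1.50·pHe)
imposed through the per-level baseline F0 (the brightness scale is
anchored at the most acidic level so every cell stays above the detection
floor); and 50 replicate growth series at a 32-h doubling time. The
decay-phase amplitude exponent is *implied* by these laws rather than
imposed, so its recovered value is reported as a derived quantity. These
sizes keep the full run around a minute on one CPU while leaving the
Monte-Carlo standard errors well inside the tolerances being checked.

## Known limitations

* The imaging model has no PSF, so A(L)/W(L) accuracy on real, blurred
  cells will be limited by optics, not by the extractor.
* Track linking has no gap closing; a missed detection splits a track.
  Dim early frames can therefore shorten the usable pre-F1 span.
* The decay-end refinement assumes the kneed-exponential family; decays
  that genuinely never end within the record fall back to the trace
  minimum, whose timing then reflects the recording length.
* Finger analysis assumes roughly parallel fingers; strongly curved
  radial patterns would need a curved-axis generalisation.
* The BCECF calibration models a single protonation step; dye loading
  artefacts (organelle sequestration, leakage) are not represented in the
  generator, so calibration tests validate the fitting machinery only.
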