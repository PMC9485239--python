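# Methods

This note documents the models, parameter choices and numerical details
behind `granuletrack`, and what the synthetic tests do and do not show
about real data.

## Acquisition model and coordinate conventions

The analysis assumes stroboscopic wide-field imaging of sparse
photoactivated emitters: 130 nm pixels, a frame cycle Δt = 6.742 ms, and
a granule-marker control image every 200 frames.  All positions are in µm
with the origin at the outer corner of the top-left pixel; pixel (i, j)
covers the half-open square [j·p, (j+1)·p) × [i·p, (i+1)·p), x runs along
columns and y along rows, frames are 0-based.  The same convention is
used by the simulator, the localizer, the raster maps and the region
masks, so coordinates round-trip without half-pixel surprises.

## Synthetic scenes

The simulator generates what the analysis assumes, with parametric
geometry for reproducibility: an elliptical cell (semi-axes 8.5 × 6.0 µm)
containing an elliptical nucleus, disk-shaped stress granules (radius
0.45–0.8 µm) drifting at ~0.2 nm/frame, disk-shaped slow-diffusivity
patches (default one patch, radius 1 µm, D = 0.1 µm²/s inside), and
point-like binding hotspots (radius 50 nm, binding probability 0.5 per
visit, geometric dwell with release probability 0.1/frame).

Emitter motion is a three-component Brownian mixture — per-axis Gaussian
steps of variance 2·D·Δt with D ∈ {0.05, 0.5, 5.0} µm²/s at fractions
{0.2, 0.3, 0.5} — reflected at the cell outline (radial folding in
elliptic coordinates, which preserves stationarity for the step sizes
involved).  Inside a patch the local patch coefficient replaces the
population coefficient.  Photoactivation is a Poisson arrival process
(default 1.5 emitters/frame, giving ~15 concurrently active emitters,
≈ 0.09 spots/µm² — spots stay well separated); bleaching is geometric
with mean track lifetime 10 frames.  Because step size depends on the
local coefficient (Itô convention, no drift correction), slow patches
accumulate density at stationarity — the same enrichment that makes
patches visible as localization hotspots in real maps.

Rendering draws each emitter as a 2-D Gaussian PSF (σ = 1 px, 200 peak
photons) over a 20 photon/px background, applies Poisson shot noise and
Gaussian read noise (σ = 2 ADU, offset 100), as uint16.  The control
channel renders the cell, nucleus and granule disks at different photon
levels.  Deliberately not modelled: motion blur within the 5 ms exposure,
EMCCD excess noise, triplet photophysics, 3-D defocus, stage drift.
Passing tests therefore validate the analysis logic and its statistical
behaviour, not robustness to those instrument effects.

## Detection, localization, linking

Detection band-passes each frame with a difference of Gaussians
(σ = 1.0/2.5 px) and keeps local maxima whose filtered amplitude exceeds
`threshold_factor` (default 2) times a robust noise scale.  The noise
scale is 1.4826 × MAD of the **raw** frame: the band-pass attenuates
uncorrelated pixel noise roughly 3.5-fold, so a factor-2 threshold on the
raw scale sits near 7 filtered-noise σ — blank frames stay essentially
free of false positives while spots down to peak SNR ≈ 5 are accepted.
(Thresholding at 2× the *filtered* image's own MAD would fire on hundreds
of noise maxima per frame; the detection filter of the original tracking
software is not published in detail, so this stand-in is calibrated by
its false-positive behaviour.)

Localization fits a 2-D Gaussian (amplitude, center, width, offset) by
batched damped Gauss–Newton least squares in a 7 × 7 px window; border
candidates are dropped.  On noise-free spots the fit recovers positions
to < 10⁻³ px; at peak SNR 8 the per-axis RMSE is below 0.3 px.

Linking is greedy nearest-neighbour: per frame pair, candidate links
within 5 px are accepted in ascending distance order, each side matched
at most once.  Direct (frame-to-frame) links are resolved before
gap-bridging links; one gap frame may be bridged, with the same radius,
only by tracks that already hold ≥ 2 localizations; tracks shorter than
3 localizations are discarded.  Ambiguity resolution is deterministic and
order-independent, and a naive quadratic re-implementation of the same
rules serves as an equivalence oracle in the tests.

## Region assignment

Granule masks come from the control channel: each control frame is
averaged with its predecessor (2-frame moving average; the first frame is
used as-is), optionally blurred (σ = 2 px, intended for map-type
analyses), thresholded at the 0.995 quantile inside the cell (the
reference procedure states only an "intensity-based" threshold, so the
value is configurable, with an absolute mode), and cleaned of components
below 4 px.  An optional 1 px dilation deliberately overestimates granule
outlines so granule-edge signal does not leak into the cytoplasm pool.
Localizations are labeled granule > nucleus > cytoplasm > outside, using
the granule mask of the nearest-in-time control frame (ties to the
earlier frame); polygons are closed sets, so boundary points belong to
the inner region.  Tracks are split into maximal single-region sub-tracks
and the crossing link is excluded from both regions' jump pools (it is
kept for shuttling, where the crossing is the observable).  Cell and
nucleus outlines are accepted as polygon JSON; an automatic Otsu fallback
on the time-averaged control channel exists for synthetic data and is not
part of the reference procedure.

## Jump-distance mixture fitting

Jump distances r of 2-D Brownian motion are Rayleigh distributed; a
mixture of m populations has CDF 1 − Σᵢ Fᵢ exp(−R²/(4DᵢΔt)).  Only the
first 5 consecutive-frame jumps of each (sub-)track enter the pool (gap
links are skipped without consuming the quota), which limits the
over-representation of slow and bound molecules whose tracks survive
longer; an all-jumps mode exists for comparison, and on fixtures where
slow tracks are long, D_eff(first-5) ≥ D_eff(all) as expected.

The empirical CDF is built on a 1 nm grid and fitted by least squares
with hard constraints Fᵢ ≥ 0, ΣFᵢ = 1 (stick-breaking parametrization)
and Dᵢ > 0 (log parametrization), uniform residual weights.  Twenty
multi-starts combine log-spaced coefficient triplets around a
half-CDF-quantile moment estimate with Dirichlet-drawn fractions (fixed
seed); best SSE wins, ties broken toward the smaller D₁.  Reported per
fit: SSE, adjusted R² (the basis for choosing m = 3 over 1 or 2), and
95 % CI half-widths from the Jacobian at the optimum via the delta
method.  The localization-error term is not part of the model, so very
small coefficients are biased upward by ~σ_loc²/Δt; this mirrors the
reference model and is documented rather than corrected.

Movie-level QC drops fits with fewer than 30 jumps, then — within each
(region, condition) group — fits whose error exceeds 5× the group median.
"Error" is defined here as the sum of relative 95 % CI half-widths over
all fitted parameters: scale-free, and large whenever any parameter is
ill-constrained.  Aggregation reports movie-wise means and sample (n−1)
standard deviations.

## TALM and diffusion maps

Analysis maps use a ×3 up-scaled grid (43 nm bins); a coarser ×2/65 nm
grid mentioned for display purposes is supported but not the default.
TALM increments exactly one bin per tracked detection (Σ bins = number of
detections, asserted).  The diffusion map bins squared consecutive-frame
jump distances at the jump's **start** position (start vs midpoint is
immaterial at 43 nm and start is deterministic), averages all entries in
the 3 × 3 bin window around each bin, and converts via D = X/(4Δt);
windows without entries are NaN.

Patch segmentation applies, in order: threshold D < 2 µm²/s,
8-connected component filter at ≥ 50 px, morphological closing with a
disk of radius 3 px, and hole filling so enclosed fast pixels join the
patch.  The pipeline is idempotent on its own output.  The 50 px minimum
is applied literally on the configured grid (50 × 43 nm px ≈ 0.09 µm²)
and the resulting areas are reported in µm² rather than asserted against
any nominal value.  Patch coverage divides the patch area inside the
granule-free cytoplasm by the cytoplasm-minus-granules area.

Voronoi clustering tessellates all detections, discards unbounded hull
cells, keeps cells with areas in the lower quartile, groups kept cells by
shared Voronoi edges (not vertices), and calls groups of ≥ 80 cells
clusters; cluster area is the summed member-cell area and the equivalent
circle diameter is 2·√(area/π).  A brute-force connected-component search
over the same tessellation is the test oracle.

## Kinetics

Bound/free segmentation uses a 2-state hidden Markov model with Rayleigh
emissions on jump magnitudes (the magnitude of an isotropic Gaussian
step), trained by Baum–Welch over all tracks of a movie with sequences
broken at gap links, and decoded by the most-probable path.  The bound
state is canonically the smaller emission scale; if the two scales
collapse the movie has a single effective state and all links are labeled
free.  On non-convergence the labels fall back to the crossing point of
the two emission densities (flagged).  The published description of this
classification is brief, so this concrete construction is a
reconstruction; on well-separated fixtures (D 0.01 vs 2 µm²/s,
stay-probability 0.95) it recovers ≥ 90 % of link labels and degrades
monotonically as the states merge.

Turning angles are computed between consecutive free links within one
segment when both jumps exceed 0.13 µm and neither spans a gap, folded to
[0°, 360°).  The fold-anisotropy f₁₈₀/₀ counts angles in the closed
windows 180° ± 30° versus 0° ± 30° (the forward window wraps);
uncertainty is the STD over 50 resamples of half the angles drawn without
replacement (angle-level resampling; track-level is available).  A zero
denominator yields NaN, never infinity.  Isotropic motion gives f → 1;
motion confined to 150 nm disks gives f well above 1.3.

Shuttling uses whole free segments across borders (bypassing region
splitting on purpose — the crossing is the point): a segment whose first
and last localizations lie on opposite sides of the granule boundary
counts as entering or leaving; totals are normalized by the movie-mean
granule area, and the entering fraction is reported.  For stationary
diffusion across a static boundary the entering fraction is 0.5.

## Problem sizes used in the tests

Unit and property tests run on frames of 32–160 px and track ensembles of
10²–10⁴; the Brownian-symmetry check uses 2,500 tracks × 20 steps
(~25,000 angles); the mixture-recovery check uses 10,000 jumps; the
end-to-end regression simulates three movies of 2,000 frames at the
default activation rate, a scale chosen so the whole suite completes in a
few minutes while keeping per-region jump counts (~10³–10⁴) in the regime
where the fits are stable.

## Known limitations

* **Radius-capped nearest-neighbour linking truncates fast motion.**
  With a 5 px (0.65 µm) radius at Δt = 6.742 ms, about 4 % of the jumps
  of a D = 5 µm²/s population exceed the radius; those jumps are lost and
  the affected tracks break (fragments under 3 localizations are then
  discarded, and at finite density the freed localizations can
  mis-connect to nearer neighbours).  On synthetic ground truth this
  depresses region-wise D_eff by ~5–7 % relative to fits on the true
  tracks — re-fitting ground-truth tracks broken at the same radius
  reproduces most of the gap.  The bias is inherent to the tracking rule,
  not to its implementation here; it is visible in the end-to-end
  regression precisely because synthetic ground truth makes it
  measurable, and it exceeds the movie-to-movie spread of homogeneous
  long synthetic movies (~1 %), while remaining well inside the
  movie-wise spread reported for real cell ensembles (~15–20 %).
* The mixture fit ignores localization error, biasing the smallest
  coefficient upward by roughly σ_loc²/Δt.
* Quantile-based granule thresholding assumes granules occupy less than
  the excluded quantile of the cell area; very large granule loads need
  the absolute-threshold mode.
* The simulator omits motion blur, EMCCD excess noise and 3-D effects;
  conclusions about detector-level robustness cannot be drawn from these
  fixtures.
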