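# Methods

This note records the models implemented in `visacuity`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic-data
validation does and does not demonstrate.

## Synthetic retinas

A ground-truth retina is an inhomogeneous Poisson point process on a
whole-mount outline. The intensity field is

```
D(x) = baseline + sum_k area_k(x) + streak(x),    D(x) = 0 in the optic disc,
```

where each *area* is an anisotropic Gaussian (centre, principal-axis sigmas,
orientation, amplitude) and the *streak* is a ridge with a Gaussian profile
perpendicular to a line segment (`half_width` is the profile sigma). This is
the simplest parametric family that reproduces the topography reported for
small poeciliid fishes: an elongated centro-temporal area holding the peak,
a smaller nasal area, and a weak horizontal streak. Cells are drawn by
rejection thinning against the field's analytic upper bound (baseline plus
the sum of component amplitudes), which is exact for any parameterisation.

The default fixture (`default_retina_spec`) is an elliptical outline of
~30.4 mm² with baseline 5,000 cells/mm², a centro-temporal area of amplitude
31,000 (field peak ≈ 36,200 cells/mm²), a nasal area of 12,000, a streak of
3,000, and a 0.25 mm optic-disc hole; its expected total is ≈213,000 cells.
These magnitudes match the totals (~214k), peak densities (27k–37k
cells/mm²) and retinal areas typical of adult swordtail-sized fish, so the
stereology runs at realistic counts per frame (~25 cells in a 60×60 µm
frame on average, ~130 at the peak).

What the generator does *not* emulate: histological shrinkage, staining
variability, mis-classified displaced amacrine cells, or spatial
autocorrelation beyond the smooth parametric field. Passing tests therefore
demonstrate correctness of the estimators under the stated point-process
model, not robustness to histology artefacts.

## Optical fractionator

Sampling is systematic uniform random: a square grid with step
`g = sqrt(area / target_sites)` (expected in-outline sites = target) and an
origin drawn uniformly within one grid cell. Counting frames (default
60×60 µm) sit at the grid nodes and use the unbiased-frame edge rule —
left/bottom edges forbidden, right/top inclusive — so a tiling design
(`asf = 1`) counts every cell exactly once. Frames that only partially
overlap the outline are retained at full frame area and flagged; section and
thickness sampling fractions are 1 (whole-mounted cells lie in a single
layer). The total estimate is `N = sum(Q) / asf`.

Precision is the Scheaffer CE: the relative standard error of the estimated
total under simple random sampling of `n` frames from the `T` frames tiling
the outline, with finite-population correction,

```
CE = sqrt((1 - n/T) · s² / n) / q̄ .
```

`T` is computed as the number of frame-sized tiles whose centre falls inside
the outline (≈ area / frame area). This is the only reading under which a
census (`asf = 1`, `n = T`) gives CE = 0 identically; counting sampling-grid
nodes instead would make CE vanish for every systematic design. The
estimator variant is recorded in the output metadata (`scheaffer-srs-fpc`)
so alternatives can be compared.

Peak density is estimated by re-sampling a window of one grid cell padded by
one step around the hottest site, with the same frame and half the grid
step; the reported value is (max frame count)/(frame area). Because it is a
maximum over ~36 Poisson counts, it overshoots the true field peak by
~10–15% at fixture densities (sd of a frame count at the peak is ~9%); the
Monte-Carlo test bounds the median overshoot at 15%. Users who need an
unbiased peak should smooth first and read the map maximum, which
conversely *under*-estimates sharp peaks.

## Topographic maps

Site densities `d_i = q_i / frame area` are smoothed with an isotropic
Gaussian kernel onto a raster clipped to the outline. The smoother is the
Nadaraya–Watson ratio

```
D(p) = Σ d_i K(p - x_i) / Σ K(p - x_i),
```

chosen over per-site (Diggle-style) mass renormalisation deliberately: the
ratio form is exactly flat for constant site densities everywhere including
the boundary (the shared denominator renormalises the kernel mass that
leaks outside the outline), whereas per-site renormalisation conserves mass
exactly but biases the boundary low by tens of percent. The cost is that
map mass is conserved only approximately — to within ~2% on regular
designs, driven by the mismatch between `n·g²` and the outline area — which
the test suite checks against the fractionator total at 5%.

Defaults: bandwidth `sigma = grid step` ("auto"), matching the sampling
resolution; raster pixel = grid step / 4 (sub-grid peak localisation at
modest memory); contour step 5,000 cells/mm². Peaks are the raster argmax
with row-major tie-breaking and a tie flag; contours come from marching
squares on the NaN-masked raster, so every polyline is closed or terminates
on the outline. Coordinates are mm with temporal = +x for right eyes; left
eyes are mirrored at annotation time.

## Anatomical acuity

`alpha = (180/pi)/f` degrees per mm of retina with `f = 2.55 · lens
radius`; acuity `= sqrt(D) / (2·alpha)` cpd assuming a square cell lattice
(two cells per cycle). The small-angle form is the default because it
reproduces the canonical ~3 cpd result for a 1.41 mm lens and 36,389
cells/mm²; an `arctan` variant (`alpha = 2·arctan(0.5/f)`) is selectable
and agrees with the small-angle form to better than 3% for focal lengths
above ~1.7 mm. A `spacing_correction` factor is exposed for hexagonal-
lattice assumptions but defaults to 1.

All stimulus/distance conversions use flat-target geometry
(`period = 2·d·tan(theta/2)`); drum curvature at 17.5 cm and ≤15 mm periods
alters periods by <0.3% and is ignored. The grey-matching helper implements
both the arithmetic midpoint `(white+black)/2` (default) and a "half-range"
convention `(white-black)/2`; for the standard 91%/6% calibration these give
48.5% vs 42.5%, and both are always reported so the discrepancy between
conventions stays visible.

## Acuity filtering of images

Images are filtered in the 2-D Fourier domain. Each frequency bin maps to
cycles/degree through the image's angular size (`2·arctan(w/2d)` per axis,
so portrait/landscape rasters are handled anisotropically). The `sharp`
filter zeroes everything above the cutoff and is exactly idempotent; the
`smooth` filter attenuates by `exp(-3.56 (nu/nu_c)²)`, the Gaussian
convention of acuity-visualisation tools (the constant is recorded in the
module). The DC term is never touched, so mean intensity is preserved
exactly before clipping; output is clipped to the input's valid range
(Gibbs overshoot can clip — tests that assert exact DC preservation use
images with headroom). Linear intensity is assumed throughout; gamma
handling is out of scope.

## Behavioural scoring

Optomotor: stress-flagged rotations are discarded first. A rotation is
individually positive on eye tracking or at least a half-turn in the
stimulus direction; a frequency is positive when ≥3 usable rotations are
positive. When fewer than three rotations survive the stress exclusion the
requirement degrades to "all usable positive" and the block is flagged
low-confidence — the most conservative reading of a 3-of-4 rule under
missing data. The acuity limit is the finest positive frequency, applied
literally across non-monotone profiles (flagged); subjects positive on the
grey control are marked invalid.

2AFC: per-frequency proportions with exact Clopper–Pearson intervals and a
side-balance statistic. The criterion is either the exact one-tailed
binomial criterion for the session's n (at n=15, alpha=0.05 this is 12/15 =
0.80; 11/15 has tail probability 0.059) or a fixed replication constant
such as 0.73 — both are supported because published work commonly uses
70–75% conventions that are close to, but not identical with, the strict
exact-binomial cut. When no count is significant (n ≤ 4 at alpha = 0.05)
the criterion saturates at perfection (n/n).

The acuity limit is reported as an interval, never a point: `last_above` is
the last frequency before the first *sustained* drop below criterion (a
drop at the final tested frequency counts as sustained), `first_below` the
next tested frequency. A single isolated dip followed by recovery is
skipped and flagged non-monotone rather than treated as the crossing;
headline estimates never come from fitting a continuous psychometric
function (the logistic model lives only inside the simulated observers).

## Simulated observers

`P(correct | f) = chance + (1 - chance - lapse) · logistic(slope · (log T -
log f))` — a logistic on log-frequency, so the threshold parameter is
directly in cpd and the curve is non-increasing in frequency. Optomotor
tracking switches from `1 - lapse` below threshold to a small false-positive
rate above it. Defaults: slope 6, lapse 0.02, false-positive 0.02, stress
rate 0.05 (matching the ~5% of rotations excluded for stress in practice).
With these settings and 200 trials per frequency on the standard ladder
(0.2–6 cpd), observers with thresholds of 1.5 and 2.5 cpd are bracketed
into (1, 2) and (2, 3) cpd respectively in ≥95% of replicates — the
parameter-recovery property the acceptance tests assert.

## Statistics

`kruskal_wallis` (scipy, tie-corrected, chi-square reference) adds an exact
permutation p-value for total n ≤ 8 by full enumeration. Note the two can
differ by more than a few hundredths at such sizes — the permutation
distribution is discrete with granularity 1/20 at n=6 — so the exact value
is validated against an independent brute-force enumeration rather than
against the chi-square approximation. `variance_ratio_test` is the
two-sided F-ratio. `linear_model_drop1` fits `response ~ continuous *
factor` by OLS and tests the interaction against the additive model; if
p ≥ 0.05 (configurable) the additive model is refit and each main effect
tested by dropping it in turn (type-II style, marginality respected).
Residual diagnostics are summary moments only — normality tests and
influence measures are intentionally out of scope. The Monte-Carlo check
of interaction detection uses n=25, sex-specific slopes 4.6 vs 0.9 and
residual sd 0.35 (a clear interaction, comfortably detectable at
alpha = 0.01), with eye sizes uniform on 1.4–2.3 mm.

## Problem sizes and determinism

The validation suite runs at desk scale chosen by the package: one ~213k-
cell fixture retina shared across tests, 500 seeded designs for the
unbiasedness check, 20 seeds for the CE criterion, 50 for peak recovery,
100 replicates for psychometric recovery. Every stochastic component takes
an explicit integer seed through `numpy.random.default_rng` and reproduces
bit-identical output for identical seeds; SVG rendering pins the matplotlib
hash salt and drops the date metadata so repeated renders are
byte-identical.

## Known limitations

* The point-process model has no cell-classification error mode beyond an
  optional uniform thinning; real whole-mounts carry spatially structured
  error.
* The NW smoother trades exact mass conservation for exact boundary
  flatness; integrals agree with fractionator totals to a few percent, not
  exactly.
* Peak sub-sampling is max-statistics-biased upward by design (it mirrors
  field practice); treat the smoothed-map peak and the sub-sampled peak as
  bracketing the truth.
* Optomotor simulation is a two-state (track / false-positive) caricature;
  it does not model graded tracking near threshold.
* No diffraction, accommodation or photoreceptor-sampling optics; the
  anatomical figure is an upper bound from RGC spacing alone.
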