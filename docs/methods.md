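# Methods

## The measurement model

A fixed eye disc is treated as a space-for-time record of development. The
morphogenetic furrow advances at constant velocity and founds one column of
R8 photoreceptors per `hours_per_column` (default 2 h), and cells do not
migrate afterwards, so a cell's anterior–posterior position maps linearly
to its developmental age. Each nucleus carries two fluorescence readings:
the reporter (YFP) and a histone-RFP normalizer expressed in every nucleus.
The working expression level is the ratio of mean pixel intensities,
`level = YFP/RFP`, which cancels nuclear volume, DNA content, and any
global intensity scaling; about 5% of RFP fluorescence is detected in the
yellow channel, so a reporter-free nucleus reads ~0.05 — this bleed-through
floor is documented, not subtracted, and neither is autofluorescence
background.

## Segmentation

The original nuclear-segmentation algorithm is described only through its
parameter table and stage order; this implementation commits to concrete
choices that preserve each parameter's documented role and monotonic
effect, which is the testable surface:

- **Foreground** — ISODATA (iterative-mean) global threshold, floored at
  the noise prior P5; pixels at or below P5 are always background. Images
  whose putative foreground covers most of the frame (inverted contrast)
  are rejected rather than segmented.
- **Clustering** — within each 8-connected component, intensity-weighted
  spatial mean-shift with a flat kernel of radius P3: pixels climb the
  local intensity surface and pool at its spatial modes. Adjacent
  subclusters are re-merged when their mean intensities differ by at most
  P1/20 of the foreground intensity spread; because the merge edge set
  grows monotonically with P1, the object count is provably non-increasing
  in P1. Objects smaller than P2 are merged into their nearest neighbour.
- **Concavity splitting** — the object boundary's convex-hull defects
  supply candidate neck endpoints; a cut is made along the chord between
  the two deepest, mutually distant defects when the neck width is small
  relative to the object's equivalent diameter. The acceptance fraction
  shrinks linearly in P4 (no cut is possible at P4 = 20) and the minimum
  defect depth grows with P4, so split counts are non-increasing in P4 and
  pixelation-scale concavities (~1 px) never trigger cuts. Splitting
  recurses on both halves.
- **Shrink** — erosion of each object by a disc of radius `shrink_level`
  (default 4 px) before measurement, because boundary pixels are brightened
  by light scattering; an object that would vanish is kept un-shrunk and
  flagged. Channel means are always taken over the post-shrink pixel set.
- 2-D only, per optical section; across sections a nucleus contributes only
  its widest contour (ties to the lower section index).

## Timeline calibration

R8 centroids are triangulated (Delaunay); links oriented 30–60° (inclusive)
from the anterior–posterior axis join R8s of adjacent columns in the
staggered ommatidial packing. μ is the mean |x_ia − x_ib| over retained
pairs, each unordered pair counted once. The first-column coordinate x_C1
is the mean x of the anterior-most column, found by 1-D clustering of R8
x-coordinates with gap threshold μ/2. Then t = hours_per_column/μ ·
(x − x_C1); cells anterior to column 1 get negative times.

Two numerical caveats are documented by tests: (i) the angular band filter
acquires a small selection bias (~2% of μ at 10% positional jitter) when
the nominal link angle sits near a band edge, because jitter moves long-dx
links out of the band preferentially — with the nominal angle mid-band the
estimator is unbiased; (ii) replicate alignment anchors on the fitted Hill
midpoint k, a robust stand-in for the profile inflection point, which is
only approximately translation-covariant (a +3 h shift is recovered as
about −2.7 h of offset). Alignment offsets are recorded in the calibration
output.

## Curve fitting

The progenitor trajectory is split at the moving-average peak into two
independently fitted phases. Induction: Y(t) = a + b·tⁿ/(tⁿ+kⁿ) with
a, b ≥ 0, k > 0, n ≥ 1, fitted by bounded least squares
(`scipy.optimize.least_squares`) from a small multi-start grid (a = data
minimum, b = range, k = half-range crossing time, n ∈ {1, 2, 4}, k scaled
by {0.5, 1, 2}). Data-driven upper bounds (k ≤ 3·t_max, n ≤ 12, b ≤ 20·
range) keep the fit identifiable when the rise is truncated before its
plateau. Decay: Y(t) = A + B·e^(−t/τ) with A, B ≥ 0, τ > 0, initialised
from a log-linear slope estimate; T½ = τ·ln 2 exactly.

Moving line averages are two-pass: windows of `window_cells` consecutive
time-sorted cells (default 130 progenitors, 40 differentiating cells)
slide by one cell, averaging both time and level; the output is smoothed
by a second pass with `smooth_cells` (default 20). Edge-truncated windows
are dropped. Concurrently committing photoreceptor and cone pairs (R2/R5,
R3/R4, R1/R6, C1/C2, C3/C4) are pooled into single classes throughout.

**Model comparison.** Linear, quadratic, cubic and exponential fits to the
decay are compared; R² is reported per model, but "best" is selected by
BIC rather than raw R²: over the 2–3 mean lifetimes a disc actually spans,
a cubic shadows an exponential closely enough that its extra parameter
wins raw R² on noise alone (~56% of noisy replicates in simulation), while
BIC recovers the generative exponential in ~94%.

**Bootstrap intervals.** Uncertainty comes from 1000 refits (configurable)
on random 70% subsamples drawn without replacement, warm-started at the
full-data solution. Because an m-of-n subsample shares most of its data
with the full sample, raw percentile spread underestimates the full-sample
sampling error; deviations from the full-data estimate are rescaled by
√(m/(n−m)) (the standard m-out-of-n correction) before the 2.5/97.5
percentiles are taken. Simulated coverage of the true τ at CV 0.2, n = 300
is ~95%; the uncorrected percentile interval covers only ~84%.

## Noise statistics

Both statistics use sliding windows of consecutive time-sorted cells
(default 280 progenitors, 70 differentiating cells; sample SD with n−1
throughout; truncated edge windows dropped):

- CV = SD/mean of measured levels — simple but confounds trend steepness
  with heterogeneity, so its profile depends strongly on window width;
- detrended fluctuation = SD of residuals to the fitted (Hill/exponential)
  trend, divided by the windowed trend mean — scale-free and robust to
  window width.

Spike summarisation lightly mean-smooths the profile (kernel = one tenth
of its length), takes the baseline at a quantile (default 0.25, tolerant
of elevations covering up to roughly half the profile), and reports the
dominant elevation's height, full width at half prominence, and location.
The location is the midpoint of the half-prominence interval rather than
the argmax: wide planted spikes produce plateau-shaped profiles whose
summit sample is an arbitrary point inside the plateau, while the interval
midpoint tracks the planted centre to well under an hour across window
sizes 20–500 in simulation.

## Spatial correlation

Log-transformed (natural log) R2/R5 levels are detrended in time by LOESS
— local second-degree polynomials, tri-cube weights, span 0.5, no
robustness iterations — per disc, then pooled. The smoother is implemented
in-package (no installed Python library offers degree-2 LOESS) and is
cross-checked in the tests against predictions frozen from R's `loess()`
on a fixture (RMS agreement ~0.005 on unit-scale data). Residuals are
correlated with each cell's Euclidean distance to its nearest R8 inside
sliding windows spanning 12.5 h (step 1 h, configurable): Pearson r, the
two-sided p from t = r√((n−2)/(1−r²)) on n−2 df, and explained variance
r². Windows with fewer than 3 cells are skipped with a logged warning. No
multiple-testing correction is applied across windows; outputs say so.

## The synthetic generator

`SyntheticConfig` defaults define the study conditions; all values are
recorded in every `GroundTruth`:

| parameter | default | meaning |
|---|---|---|
| `n_columns` × `rows_per_column` | 14 × 6 | R8 lattice (one column / 2 h) |
| `column_spacing_px` / `row_spacing_px` | 25 / 34 | staggered packing; adjacent-column links sit at ~34°, inside the 30–60° band |
| `hill_params` (a, b, k, n) | 0.1, 1.0, 8, 4 | progenitor induction |
| progenitor decay (A, τ) | 0.12, 20 h | changeover at 15 h, continuous with the rise |
| differentiating decay τ | 10 h | half the progenitor lifetime (2:1 ratio) |
| onsets (R8, R2/R5 … C3/C4) | 0, 8, 12, 16, 18, 22, 24 h | earliest recruits first, cones last |
| `baseline_cv` | 0.15 | multiplicative log-normal cell-to-cell noise |
| `noise_spikes` | progenitor (15 h, 17 h, +0.3); R2/R5 (10 h, 17 h, +0.3) | transient heterogeneity at the transitions; a non-finite width makes the elevation sustained |
| `bleed_fraction` | 0.05 | RFP→YFP bleed floor on the ratio |
| `r8_distance_coeff` | 0.03 /px | positive R8-distance term on log R2/R5 levels, centred at 11 px so the mean trend is unchanged; sized to be detectable at p < 0.01 in pooled 4-disc windows |
| `copy_number_scale` | 1.0 | multiplies all amplitude parameters (a, b, A, B), leaving k, n, τ unchanged |

Noise is multiplicative log-normal with unit mean, so CV is independent of
the level and spike increments add in CV. The measured ratio of a cell is
`level·noise + bleed_fraction` (the bleed floor is additive on the ratio);
ground truth records the floored expectation. Differentiating cells are
placed 4–18 px from their R8 once the local column time passes the type's
onset; progenitors are scattered uniformly (minimum separation 0.35× the
lattice pitch) extending three columns anterior of column 1 so the
induction baseline is sampled. The renderer draws each nucleus as a
uniform disk at its channel mean, blurred by a Gaussian PSF, over a
constant background with variance-equal-to-mean shot noise; mask disks are
clipped to half the nearest-neighbour distance so labels are disjoint.

What the generator does **not** emulate: optical sectioning artifacts and
3-D nuclear migration, the second mitotic wave's DNA-content variation,
spatially correlated (non-independent) noise, segmentation-relevant
texture inside nuclei, and any real biology beyond the planted structure.
Passing tests therefore demonstrate that the pipeline recovers what it
assumes — correct calibration, unbiased fits, calibrated intervals, honest
detection — not that real discs satisfy those assumptions.

## Problem sizes and determinism

Tests and the acceptance script scale simulations to what the checks need:
single discs of ~10³ cells, 4-disc pools for correlation analyses,
150–200 outer replicates for interval-coverage estimates (200 bootstrap
refits each), 100 seeds for the dosage-invariance check, and 500-seed null
simulations for p-value calibration. Every random draw descends from one
`numpy` `default_rng` seed; identical seed and configuration give
bit-identical tables, images and JSON outputs, which the end-to-end
determinism test asserts byte for byte.

## Known limitations

- The segmentation stages are a faithful-by-roles reimplementation, not
  the original unpublished algorithm; only parameter roles and
  monotonicities are asserted.
- On densely packed discs (~9 px nearest-neighbour separation at ~6 px
  nuclear radii) segmentation recovers ~70–75% of planted nuclei within
  2 px; the guaranteed count/centroid recovery holds for separations of at
  least 3× the PSF width.
- `align_samples` assumes every replicate contains an induction phase and
  anchors on the Hill midpoint (see the timeline caveats above).
- In `images` mode (user TIFF without annotations) the pipeline stops
  after quantification: cell-type labels are required downstream and
  manual annotation is out of scope.
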