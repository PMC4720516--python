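# furrow

Quantitative image analysis of transcription-factor dynamics in the
*Drosophila* eye imaginal disc.

During eye development the morphogenetic furrow (MF) sweeps across the disc
at constant velocity, founding one new column of R8 photoreceptors every
2 hours. Behind it, multipotent progenitor cells express the transcription
factor Yan in a biphasic pattern — a fast, Hill-shaped induction followed by
a slow exponential decay — while cells committing to photoreceptor and cone
fates shed Yan faster and transiently become much more heterogeneous.
Because the tissue is a natural space-for-time substitution, a single fixed
disc contains the entire trajectory: a cell's anterior–posterior position
*is* its developmental age.

`furrow` implements the complete route from confocal nuclei to dynamics,
for anyone analysing fixed-tissue reporter imaging with a spatial pseudotime
axis:

1. **Segmentation** (`furrow.segmentation`) — per-section nuclear
   segmentation driven by five documented parameters (intensity range P1,
   window size P2, spatial range P3, concavity threshold P4, noise
   intensity P5) plus boundary shrinking; across sections only the widest
   contour of a nucleus is kept.
2. **Quantification** (`furrow.quantify`) — per-nucleus channel means and
   the ratio normalization `level = YFP / RFP` against a histone-RFP
   denominator (cancels ploidy and nuclear-volume variation), plus histone
   content = intensity × nuclear size.
3. **Timeline** (`furrow.timeline`) — Delaunay triangulation of R8
   centroids, 30–60° link filtering, the mean adjacent-column x-distance
   μ = (1/n) Σ|x_ia − x_ib|, and the conversion
   t = (2/μ)(x_C − x_C1) hours; replicate discs are aligned on their
   induction midpoints.
4. **Dynamics** (`furrow.dynamics`) — moving line averages (windows of 130
   progenitor / 40 differentiating cells, smoothed with a 20-point second
   pass), the Hill induction fit Y(t) = a + b·tⁿ/(tⁿ + kⁿ), the exponential
   decay fit Y(t) = A + B·e^(−t/τ) with model comparison, and half-lives
   T½ = τ·ln 2 with subsample-bootstrap intervals (1000 refits on 70%
   subsamples without replacement).
5. **Noise** (`furrow.noise`) — two scale-free heterogeneity statistics on
   sliding cell windows (280 progenitors / 70 differentiating cells):
   CV = σ/μ and the detrended fluctuation (SD of residuals to the fitted
   trend over the windowed trend mean), plus spike localisation.
6. **Spatial correlation** (`furrow.spatial`) — LOESS detrending (local
   quadratics, tri-cube weights, span 0.5) of log R2/R5 levels, distance to
   the nearest R8, and windowed Pearson correlation (12.5-h windows) with
   t-test p-values and explained variance.
7. **Synthetic discs** (`furrow.synthetic`) — a generator that emulates the
   statistical structure above with full per-cell ground truth, plus a
   renderer producing two-channel TIFF stacks and label masks, so every
   stage is testable against known truth.

The Hill and decay fits are scikit-learn estimators (`HillRegressor`,
`ExponentialDecayRegressor`, `LoessDetrender`) and compose with sklearn
model selection; `fit_hill` / `fit_decay` / `loess_detrend` are the thin
functional equivalents.

## Worked example

```python
import numpy as np
from furrow import (SyntheticConfig, generate_disc, calibrate_furrow,
                    position_to_time, fit_decay, bootstrap_half_life)

cfg = SyntheticConfig(seed=1)                 # defaults: tau = 20 h in progenitors
sample, truth = generate_disc(cfg)

cal = calibrate_furrow(sample.r8_positions)   # mu and first-column x from the R8 lattice
print(f"mu = {cal.mu_px:.2f} px")             # mu = 25.00 px

cells = sample.cells
cells["time_hr"] = position_to_time(cells["x_px"].to_numpy(), cal)
prog = cells[cells.cell_type == "progenitor"]
fall = prog[prog.time_hr > 15.0]              # decay phase

fit = fit_decay(fall.time_hr - 15.0, fall.normalized_level)
boot = bootstrap_half_life(fall.time_hr - 15.0, fall.normalized_level,
                           n_boot=1000, seed=1)
print(f"tau = {fit.tau:.1f} h, T1/2 = {fit.half_life_hr:.1f} h, "
      f"95% CI [{boot.half_life_interval[0]:.1f}, {boot.half_life_interval[1]:.1f}]")
# tau = 33.7 h, T1/2 = 23.3 h, 95% CI [13.2, 52.1]
```

The disc was generated with a progenitor decay constant of τ = 20 h
(T½ = 13.9 h). One disc observes only ~11 h of decay — about half a mean
lifetime — so the three-parameter exponential is weakly identified and the
point estimate lands high, but the bootstrap interval is honest about it
and covers the truth. Pooling replicate discs and longer time spans (what
the pipeline and the acceptance script do) brings the estimate in: the
same fit on 500 cells spanning two mean lifetimes recovers T½ to within
a few percent.

Run everything end to end from a shell:

```bash
furrow run-all --seed 1 --outdir run1
```

which writes cell tables, rendered stacks, the furrow calibration, fitted
parameters with bootstrap intervals, noise profiles with spike summaries,
the spatial-correlation windows, and a manifest recording the seed and all
parameters.

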