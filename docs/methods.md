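# Methods

## The question and the estimation strategy

Rangeland degradation — a persistent rise in bare ground at the expense of
grazeable vegetation — can arise through two mechanisms: pixels may decline
more during environmental shocks (loss of resistance) or rebound less
afterwards (loss of recovery). The two are distinguishable from a
sufficiently long score series: if resistance is lost, the pixels that end
up most degraded show the largest score increases in shock years; if
recovery is lost, their shock responses match everyone else's but their
post-shock decreases are smaller. `rangeres` builds the score series (a
bare-ground index calibrated to field plots), quantifies both contrasts
with class-level statistics, and attributes long-term rates to
anthropogenic and environmental covariates under a spatially correlated
error model.

## The synthetic world

Because the analysis must be testable without proprietary imagery, the
package ships a generative model of the whole observation chain. Its
defaults are the package's reference study conditions and are not tuned per
experiment.

**Latent dynamics.** The true bare-ground fraction of pixel *i* evolves
annually as

    b[i,t] = clip01( b[i,t-1] + δ_i·max(0, −A_t)
                     − ρ_i·(b[i,t-1] − β_i)·max(0, A_t)
                     + γ·(w_h·h_i + w_l·l_i + w_d[d_i]) + ε_it )

with `A_t` the pixel's standardized annual rainfall anomaly, `β_i` the
baseline cover, `δ_i ≥ 0` the susceptibility (inverse resistance), `ρ_i ∈
[0,1]` the fractional recovery rate, a small chronic-pressure drift from
human density, livestock density and land-use designation (γ = 0.001 per
year), and Gaussian process noise (sd 0.01). This is the minimal model with
separable resistance and recovery terms; at `A = +1` and `ρ = 1` the whole
excess over baseline is removed in one year.

**Scenario presets.** `loss_of_resistance` draws δ as a smooth field on
[0.02, 0.12] with ρ fixed at 0.5; `loss_of_recovery` fixes δ = 0.07 and
draws ρ on [0.15, 0.90]. Everything else (baseline, phenology, covariates,
designation patches) is drawn identically, so only the dynamics separate
the two worlds, and the downstream verdict is a genuine discrimination
test.

**Rainfall.** Annual cell totals are a static spatial gradient (mean 600 mm,
sd 80 mm across cells) plus a landscape-wide interannual deviation (sd
20 mm) plus small cell-year noise (sd 10 mm); planted drought years
(defaults 2003, 2009, 2011, 2019, echoing the cadence of observed regional
droughts) subtract a coherent 50%-of-mean shortfall. Droughts are modelled
as regionally coherent on purpose: real semi-arid droughts span whole
landscapes, and coherent shocks keep shock severity independent of the
static wet/dry gradient, so class contrasts are not confounded by rainfall
geography. Interannual variability is deliberately drought-dominated
(overall CV ≈ 20%, non-drought CV ≈ 3%), which makes post-shock years
reliably recovery-capable; in records where a recovery year is itself dry,
the recovery contrast vanishes for that year (the analysis reports this
per year rather than failing). Totals are spread over months with a fixed
bimodal profile (short rains Nov–Jan, long rains Mar–May).

**Rendering.** Reflectance is a linear soil/vegetation mixture, `b·soil +
(1−b)·g(t)·veg + noise`, with seasonal greenness `g(t) = ½(1 + cos 2π(t −
φ_i))` and endmembers chosen for a generic bright-soil vs green-vegetation
contrast (soil: 0.12/0.22/0.28/0.34, vegetation: 0.04/0.05/0.45/0.20 in
Blue/Red/NIR/SWIR). This guarantees the correct index signs — BSI increases
and EVI/MSAVI decrease in `b` — which the tests verify on a noiseless
ladder. Clouds knock pixels out independently (default 10%).

**Surveys.** Plots sit at the centres of survey cells stratified by the
cross of quantile-binned mean rainfall, quantile-binned greenness, and a
grassland/woodland class (proxied in the pipeline by phenology timing so
the three layers are not collinear); allocation is even across strata
(residual plots go to the first strata in label order), neighbouring cells
are excluded, and the measurement is Binomial(100, b) point-intercept
counts in the plot's survey year (defaults 2016 and 2018, 256 plots).

**What the generator does not emulate.** Sensor cross-calibration drift,
scan-line artefacts, spatially correlated cloud fields, atmospheric
variation, fire, woody encroachment dynamics, and survey placement error.
Passing tests therefore show the *pipeline logic* is sound under a
plausible observation model, not that any particular real landscape obeys
the latent dynamics.

## Stage-by-stage choices

**Spectral.** BSI uses the four-band normalized form
`((SWIR+Red) − (NIR+Blue)) / ((SWIR+Red) + (NIR+Blue))` — the single
supported dialect. Cloud masking keeps pixels with strictly less than 10%
cloud score. Gap filling interpolates missing runs of 1–3 scenes linearly
in date, never extrapolates across series ends, and is idempotent; it is
applied to index series (not reflectance bands). Composites average valid
scenes in [1 Nov of the previous year, 1 Nov of the focal year); dates use
a 365-day no-leap calendar to keep window boundaries unambiguous.

**Features.** One annual harmonic (frequency 1/yr) is fitted per focal
window by OLS; magnitude is `√(a₁²+b₁²)` and phase `atan2(b₁, a₁) ∈ (−π,
π]`, so a pure cosine peaking at New Year has phase 0. Pixels need ≥ 3
valid scenes and a non-singular design. The 10-predictor set is {EVI, BSI,
MSAVI} × {mean, magnitude, phase} plus May–April rainfall. Standardization
uses the sample (n−1) standard deviation of the training rows, stored for
prediction time.

**BGI model.** Hyperparameters are fixed, small defaults per algorithm
(`bgi_model.DEFAULT_PARAMS`): the protocol — partitioning, repeated CV,
holdout selection — is the reproducible object, not a tuning grid.
Selection is by holdout RMSE with ties broken by holdout R² then CV RMSE.
R² is the coefficient of determination; the squared Pearson correlation is
reported alongside. "Scaled by 2016" z-scores every year's back-transformed
map by the 2016 map's spatial mean and sd; normalization to [0, 1] is
global across all years, because per-year normalization would erase the
inter-annual signal the resilience stage depends on.

**Resilience.** Aggregation is an origin-anchored 7×7 block median
(≈ 200 m from 30 m pixels); incomplete edge blocks are dropped. Tertiles
are assigned by rank of the median normalized score over the final three
years (ties broken by pixel index), so classes are even-sized by
construction and invariant to monotone transforms of the score. Shock
years are the k = 4 largest year-over-year increases of the landscape
median; non-positive "increases" are flagged weak rather than dropped.
Relative recovery is masked where |Δshock| < 0.01 normalized units to
avoid ratio blow-up. Medians carry bootstrap CIs (1,000 resamples by
default, seeded). The verdict counts a shock (or recovery) year only when
the most-vs-least Tukey contrast is significant at α = 0.05 **and** at
least 0.005 normalized units in the right direction: with hundreds of
pixels per class significance alone is nearly inevitable, so an
effect-size floor keeps ecologically negligible contrasts from driving the
verdict (effect sizes are always reported next to p-values). Majorities of
flagged years map to `loss_of_resistance` / `loss_of_recovery`; both →
`mixed`; neither → `indeterminate`.

**Trend.** The per-pixel rate is the year coefficient of OLS on
[1, year−mean, rainfall−mean], requiring ≥ 5 valid years; constant
rainfall triggers a flagged fallback to score ~ year. The covariate model
is GLS with covariance `σ²[(1−w)·exp(−d/r) + w·I]` — an exponential
(Matérn ν = ½) field plus nugget. β and σ² are profiled analytically; the
range r is searched on a fixed geometric grid (0.25–16 pixels, 9 points)
with the nugget fraction w optimized per candidate range in the kernel's
eigenbasis, which also lets repeated fits on one grid share the O(n³)
decompositions. The rainfall covariate is the pixel's long-term mean
(static in a rate-level regression); continuous covariates are z-scored,
and designation enters as dummies against the NONE baseline. Intervals are
Gaussian at 95%; "supported" means the interval excludes zero. Because
hyperparameter uncertainty is not propagated, intervals can be mildly
anticonservative — observed coverage in the recovery study sits at
90–94%. Calibration uses the exact Gaussian leave-one-out identity: PIT_i
= Φ((P r)_i / √P_ii) with P the marginal precision, summarized by a KS
distance from uniformity.

**Pipeline.** All randomness flows from one root seed through named
substreams (`rainfall`, `truth`, `dynamics`, `scenes/<year>`, …), so every
stage is independently reproducible and the artifact manifest (SHA-256 per
file) is stable across reruns. Rasters are written as plain multiband
TIFFs with row/col geometry only; tabular artifacts as CSV/Parquet/JSON.

## Problem sizes

The reference world is a 168×168 fine grid (24×24 coarse pixels) over 21
years with 12 scenes/year; the discrimination and detection studies use 20
seeded worlds per preset, and the spatial-model study 100 simulated 40×40
rate surfaces with planted effects (rainfall −0.05, human +0.015,
livestock +0.015, NP −0.04, WMA −0.02, CCRO 0 in standardized units;
spatial sd 0.02, range 2 px, nugget sd 0.02). These sizes give stable
rates while keeping any single study to a couple of minutes on one CPU.

## Known limitations

- The verdict's effect-size floor (0.005 normalized units) is a fixed
  default; landscapes with genuinely tiny but real contrasts would need it
  lowered and the pixel-level pseudo-replication addressed properly (e.g.
  block-resampled tests).
- The ANOVA/Tukey machinery treats pixels as independent; spatial
  autocorrelation is only handled in the trend stage's covariate model.
- The spatial model's range is estimated on a discrete grid and its
  uncertainty is not propagated into the fixed-effect intervals.
- Recovery is measured exactly one year post-shock; multi-year recovery
  trajectories are out of scope.
- Real-data mode expects the caller to supply cloud scores and a
  savanna/non-savanna mask; neither is derived from imagery here.
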