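# Methods

This note records the statistical model, the numerical choices and the
known limitations of `ermeta`, in the spirit of a package vignette. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Effect sizes

One *dataset* is one experiment × ER-measurement-year; it is the unit of
meta-analysis throughout. From plot-level daily fluxes (standardized to
gCO₂ m⁻² d⁻¹ with molar masses CO₂ = 44.009, C = 12.011 g mol⁻¹ and
86 400 s d⁻¹) the pipeline:

1. drops observations outside the site's growing season (default months
   {6, 7, 8}; southern-hemisphere sites configure their own set, e.g.
   October–February);
2. removes outliers beyond mean ± k·sd (k = 3) computed **once** per
   dataset with both treatments pooled. The filter is single-pass by
   construction and the pipeline applies it exactly once; re-applying it
   could remove more points. A consequence worth knowing: a lone extreme
   among n observations can deviate at most (n−1)/√n pooled sds, so a
   3-sd rule cannot fire at all for n ≤ 10 — small datasets are
   effectively unfiltered;
3. averages daily values per plot (plots, not plot-days, are the
   replication unit — using plot-days would pseudo-replicate), converts to
   gC m⁻² d⁻¹, and summarizes mean/sd/n per treatment arm;
4. computes Hedges' g with the (n−1)-weighted pooled sd and the
   small-sample factor J = 1 − 3/(4m − 1), m = n_w + n_c − 2 (the
   first-order form, not the gamma-function form: conventional, and exact
   enough at any m that matters), variance
   J²[(n_w+n_c)/(n_w n_c) + d²/(2(n_w+n_c))]; lnROM with variance
   s_w²/(n_w m_w²) + s_c²/(n_c m_c²); and raw mean differences with
   variance s_w²/n_w + s_c²/n_c.

Datasets with fewer than two plots in either arm, zero pooled variance, or
nonpositive means (for lnROM) are excluded with logged reasons — never
silently.

Warming duration (measurement year − treatment start year; 0 means the
first summer) requires a start year, which the canonical flux CSV carries
as an optional `start_year` column (or a mapping argument). Where absent,
duration falls back to 0; temporal analyses should not be run on such
data.

## The meta-analytic model

Effect sizes are modelled as

y_i = x_i′β + u_exp(i) + w_exp(i)(year_i) + u_ds(i) + e_i,

with u_exp ~ N(0, σ²_exp), u_ds ~ N(0, σ²_ds), e_i ~ N(0, v_i) (v_i known
from step 4), and w a continuous-time AR(1) within experiment:
Cov[w(t), w(s)] = τ²ρ^|t−s|, years on an integer annual index (only year
*differences* matter; estimates are invariant to shifting all years).

Fitting is by REML with the restricted log-likelihood
−½[(k−p)ln 2π + ln|V| + ln|X′V⁻¹X| + r′V⁻¹r]. Note this convention omits
Harville's +½ln|X′X| constant; R's metafor includes it, so log-likelihoods
differ by exactly that constant while all estimates agree (the test suite
cross-checks β, SEs, variance components, QM and QE against `rma.mv`
through Rscript).

Numerical choices:

- variance components are optimized as log-variances and ρ as a logit
  (upper bound 1 − 10⁻⁶), with four deterministic starts — near-zero,
  a method-of-moments seed split across active components, and ×4 / ×¼
  perturbations — L-BFGS-B then a Nelder–Mead polish; REML surfaces here
  can be multimodal in ρ;
- a diagonal fast path handles models with no experiment-level or CAR
  term (k×k solves become O(k));
- singular covariances return a −10³⁰⁰ sentinel so optimizers step back
  rather than crash;
- components estimated below 10⁻⁷ (or ρ above 1 − 10⁻⁵) are flagged as
  boundary estimates in `MetaModel.boundary`; with k − p ≤ 2 expect them;
- β is profiled (GLS) rather than jointly optimized; ML refits serve only
  AIC and McFadden's pseudo-R² = 1 − ll_ML(model)/ll_ML(null), both models
  on the identical complete-case subset.

Q (total, against the fixed-effect weighted mean, w_i = 1/v_i), QE
(residual, same weights, of the moderator design) and Qm (Wald chi-square
on non-intercept coefficients of the fitted random-effects model) follow
the conventional forms; no Knapp–Hartung or robust variance is offered.

## Moderator programme

Single-factor metaregressions keep moderators on their raw scales (slopes
stay interpretable; the upscaling needs raw-scale coefficients), dummy-code
categoricals against the first level, and enforce complete cases per
model — `n` is reported with every fit and differs across moderators by
design. Age classes partition duration as closed integer intervals [0,4],
[5,9], [10,14], [15,∞) (the only partition consistent with whole-year
durations). The temporal analysis reports cell-means class estimates with
per-class z-tests, an omnibus Qm for class differences from the
treatment-coded model, within-class duration slopes (NA below 2 datasets)
and the overall slope. A pairwise moderator correlation screen is exported
as a report; nothing is auto-excluded. No multiplicity correction is
applied across single-factor models — the family size is visible in the
output, and readers should treat p ≈ 0.05 results accordingly.

Predictions are fixed-effect only: mean x*′β̂ and SE √(x*′V̂_β x*). No
random-effect variance is added, because the upscaling asks where the mean
response surface sits, not where a new experiment would.

## Spatial upscaling

Grid inputs are TN/SOC/BD mean, 5th and 95th percentile layers per depth
interval (ESRI ASCII grids — a plain-text, lossless raster format — one
file per layer; % by mass for TN/SOC, g cm⁻³ for BD) plus a baseline
respiration grid (gC m⁻² yr⁻¹). Per cell:

- depth intervals within 0–60 cm are *mineral* iff TN ≤ 0.01 g/g and
  SOC ≤ 0.1 g/g and BD ≥ 1 g/cm³. The thresholds bound the mineral side
  because organic horizons are carbon- and nitrogen-rich and light; the
  directions are config-overridable. TN and SOC (and their percentile
  bands) are thickness-weighted over the mineral intervals; cells with no
  mineral interval carry no prediction;
- sd = (q95 − q05)/(2 × 1.644854…) converts the percentile band to a
  normal sd;
- (TN, SOC) pairs are drawn from a bivariate normal (correlation 0.8273)
  truncated below at 5 % of each mean. Truncation shifts means, so the
  location is adjusted by alternating per-variable scalar root-finds on
  the *bivariate* lower-truncated normal mean identity (Rosenbaum
  moments). The univariate identity is not enough: with ~17 % of the TN
  mass cut and correlation 0.83, the partner's truncation shifts the TN
  mean by over 1 %; the bivariate adjustment leaves <0.1 % bias. A second
  consequence of truncation is intrinsic and not adjustable: the Pearson
  correlation of the *accepted* sample is attenuated below the Gaussian
  parameter (≈0.76 at those settings), approaching 0.8273 only as
  truncation becomes negligible. Cells whose adjustment cannot bracket a
  root (sd ≫ mean) fall back to clipped untruncated draws and are flagged;
- C:N is SOC/TN per draw, bias-corrected by one of 100 bootstrap linear
  regressions of reported-vs-derived C:N (cycled over draws). The
  repository ships no real scatter; `cn_scatter_from_drivers` generates a
  synthetic one (labelled as such) and `bootstrap_cn_regressions` accepts
  any user-supplied pairs;
- each draw yields a prediction mean and SE on the lnROM scale; draws are
  combined on that scale (the model's native one) with the equal-weight
  normal-mixture SD, then transformed: per cent change 100(e^μ − 1), its
  sd by the delta method 100e^μ·sd, cv = sd/|mean| with an NA guard below
  |mean| < 10⁻⁶, absolute change = baseline × (e^μ − 1);
- the uncertainty decomposition reruns the combination with the
  coefficient covariance zeroed on the *same* draws (shared substreams by
  construction), reporting input-only/combined sd ∈ (0, 1];
- regional totals sum area × flux × 10⁻¹⁵ to PgC yr⁻¹; the Δ-sd treats
  cells as independent, a deliberate simplification — per-cell percentile
  bands carry no spatial error covariance, so any imposed correlation
  would be invented. Regional sds are therefore best read as lower bounds.

Every cell draws from its own seed substream (`SeedSequence(seed,
spawn_key=(cell_id,))`), so results are bit-reproducible and independent
of evaluation order; n_draws defaults to 100 and is configurable.

## Synthetic data generator

The generator emulates a multi-site warming-experiment synthesis with
known truth: 28 sites ⊃ 56 experiments ⊃ 136 dataset-years by default,
1–13 measurement years per experiment (durations geometric-ish, mean ≈ 3
extra years, capped at 25), 3–8 plots per arm, per-dataset true effect
μ + u_exp + u_ds + CAR(year) + Σ slope·driver with defaults μ = 0.57,
σ²_exp = 0.1, σ²_ds = 0.05, τ² = 0.05, ρ = 0.6. Daily fluxes are lognormal
multiplicative noise (σ_log = 0.25, 8 days per plot) around normal
plot-level means (control 3.0 ± 1.5 gCO₂ m⁻² d⁻¹ — a tundra-plausible
scale whose CV ≈ 0.5 makes an SMD of 0.57 correspond to roughly +30 % ER);
warmed plot means are offset by g_true times the effective between-plot sd
(plot variance plus the daily-noise contribution to plot means, solved by
a small fixed point because the lognormal noise is mean-dependent). This
makes the *computed* effect sizes unbiased for the truth, which the suite
verifies by regressing computed on true effects.

Driver tables realize moderators on natural scales (TN % lognormal around
0.5, C:N ≈ 15 ± 4, change-effects as noise-free summary blocks whose
Hedges g equals the latent value); TN level and TN change are generated
negatively correlated (default −0.43: nutrient-poor sites change more);
missingness is configurable per driver, with co-measured soil drivers
sharing their missingness draw (so TN + C:N complete cases resemble a real
soil-sampling pattern rather than the product of independent rates).
Treatment microclimate drivers default to +1.4 °C air, +0.4 °C soil and
−1.6 percentage points moisture. Soil rasters are smoothed random fields
whose percentile bands are built from a known sd (so the sd identity
inverts exactly), with a configurable organic-cell fraction.

What the generator does **not** emulate: real geography and climate
covariance, seasonal flux curves and measurement-method differences,
spatially correlated soil errors, non-normal plot effects. Passing
recovery tests therefore demonstrate the estimators are correct for the
stated model, not that the model captures every feature of field data.

## A known property worth stating plainly

The sampling variance of Hedges' g contains the dataset's own d². With
3–8 plots per arm, the inverse-variance weights are then negatively
correlated with the estimates, and the weighted pooled mean of an SMD
meta-analysis sits systematically below the truth even when every
individual effect size is unbiased — around −0.06 at these sample sizes
and heterogeneity ≈ 0.15, shrinking to ≈ −0.02 at 10–20 plots (the suite
quantifies this with both the full pipeline and an ideal-data
normal-theory simulation). This is a property of the standard estimator,
shared by any implementation of it, and it is why the full-pipeline
recovery test distinguishes "the engine is unbiased given effect-level
data" (it is; tested) from "the weighted pooled SMD is unbiased at tiny
plot counts" (it is not, for anyone). Applied work should read pooled
SMDs from small-plot syntheses with that in mind; the lnROM pathway is
less affected because its variance does not involve the effect itself as
directly.

## Limitations

- Wald/χ² inference throughout: Qm is mildly liberal at moderate k
  (measured ≈ 0.05–0.07 at k = 50 under the null, seed-dependent); no
  Knapp–Hartung adjustment by design.
- Fixed-effect prediction SEs exclude random-effect variance; upscaled
  uncertainty quantifies the mean surface only.
- Regional sd assumes independent cells (see above).
- The CAR index is whole years; sub-annual repeated measures are out of
  scope (daily values are averaged before anything temporal happens).
- No gap-filling, diurnal modelling, or GPP handling; inputs are assumed
  to be daytime growing-season ER.
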