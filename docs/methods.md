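# Methods

This note documents the statistical models, conventions, and numerical
choices behind `seedperf`, and what the synthetic-data studies do and do
not demonstrate.

## Data model and measurement conventions

Census rows are one measurement of one tagged seedling at one census:
height (cm), leaf count, alive/dead status, rooting substrate, subplot.
Heights sit on a 0.5 cm grid, reflecting field practice of rounding
small-seedling measurements to equalize over- and underestimates.
`round_measurement` rounds to the nearest 0.5 cm with exact ties
(x = k·0.5 + 0.25) rounding **up**; the tie rule is a package convention
(any fixed rule equalizes errors on continuous data, where exact ties
have measure zero) and lives in a single function. Validation enforces:
positive on-grid heights for live records, strictly increasing census
dates per tag, no duplicate (tag, date), and no record after death — a
dead seedling is recorded once, retaining its last measured height.

One CSV dialect only (comma, UTF-8, header, ISO-8601 dates), so
read/write round-trips are byte-stable and pipeline outputs are
diffable.

Tree community statistics use basal area π(dbh/2)² per stem (circular
stems, the standard forestry convention; DBH < 1 cm stems are outside
the tree census).

## Microhabitat discretization

Five axes, 18 categories: tertiles of TPAR, slope, and elevation over
subplots; three fixed aspect sectors; six substrates. Choices:

* Tertile cuts are the empirical 1/3 and 2/3 quantiles (linear
  interpolation) over subplot values, overridable in config with
  explicit cuts when a study's own cut points are known. TPAR is
  categorized on the raw transmittance fraction (no log transform).
* Intervals are half-open with ties falling in the lower bin, so every
  value gets exactly one label deterministically. The 242° aspect
  boundary belongs to W–NW.
* Heavily tied inputs whose tertile quantiles coincide cannot form
  three levels and are rejected rather than silently merged.
* Substrate is read from the seedling's first record; composite
  multi-axis habitats are out of scope (sample sizes in the motivating
  design do not support them).

## Performance metrics

RGR = (ln S₁ − ln S₀)/Δt with Δt in years of 365.25 days, computed from
the **first to the last live measurement** (census intervals are
irregular, and the two-point estimator is unbiased for the latent
per-seedling growth rate when growth is log-linear). Eligibility: ≥ 2
live measurements and initial height strictly below 10 cm (equalizing
starting sizes; a 10.0 cm initial height is excluded). The height
filter applies to RGR only — survival keeps all tagged seedlings, which
is why survival sample sizes exceed RGR sample sizes.

Mass and leaf-area sizes come from per-species OLS fits on the log
scale (ln mass ~ ln height; ln area ~ ln height + ln leaf count; ≥ 4
harvest records per species). Predictions back-transform by plain
exponentiation with **no** smearing/Baskerville correction — a known
systematic choice (predicted medians, not means); since RGR is a
difference of logs divided by time, any multiplicative bias cancels
from RGR entirely. R² is reported on the fitting (log) scale.

First-year survival is read once per seedling: status at the first
census 330–430 days after its first record, else at the nearest census
after 365 days. A seedling observed dead before any qualifying census
scores 0 (a first-year death); one never observed again after tagging is
undefined. The window is configurable; the default brackets the ~7–13
month census spacing the design emulates. Each seedling's clock starts
at its own first measurement, so later recruits contribute too.

## Inference within a microhabitat

All comparisons share one model structure: fixed species effects
(reference coding), one random intercept per subplot.

**Gaussian (RGR).** REML with the variance ratio λ = σ_u²/σ_e² profiled
out. The single-grouping-factor structure gives closed-form GLS pieces
from per-subplot sufficient statistics (no n×n matrices): with
w_g = λ/(1 + n_g λ),

    X'V*⁻¹X = X'X − Σ_g w_g (X'1_g)(X'1_g)',   log|V*| = Σ_g log(1 + n_g λ).

The REML criterion is evaluated on an 81-point log-λ grid spanning
e⁻¹² to e⁸ and refined by bounded scalar minimization around the best
grid point; if the λ = 0 boundary (OLS) is at least as good, the fit
falls back to OLS exactly. A returned fit's objective therefore
dominates any grid value — asserted as a test property against a
200-point grid.

**Binomial (survival).** Logistic random-intercept model by maximum
likelihood under the Laplace approximation: per-subplot scalar Newton
iterations find each conditional mode (vectorized across subplots,
warm-started), and BFGS optimizes fixed effects plus log σ_u² with
fixed zero starting values, so fits are deterministic. Complete
separation (a species all-alive or all-dead) is detected and flagged,
and a small ridge (10⁻⁴) keeps estimates finite; the flag is carried in
the fit object. Standard errors come from the inverse numeric Hessian.

*Known limitation:* for sparse binary clusters (few observations per
subplot) the Laplace variance estimate is biased downward relative to
exact maximum likelihood, and when the variance estimate is interior
the fixed effects can differ from the exact-ML fixed effects by up to a
few 10⁻² on the logit scale. The oracle-equivalence study therefore
compares Laplace and adaptive-quadrature fits at a known, matched
random-intercept variance (SD 0.25), where agreement is ~3×10⁻⁴; the
free-variance discrepancy is the approximation itself, not an
implementation artifact, and is absorbed into the wider coverage band
accepted for binomial contrasts (88–98% vs 90–98% Gaussian).

**LS-means and contrasts.** With species-only fixed structure, the
LS-mean of species s is intercept + effect_s at random effect zero;
binomial LS-means are also reported as logistic-transformed
probabilities. Pairwise contrasts use Wald z statistics with two-sided
standard-normal p-values (the asymptotic convention for mixed-model
contrasts; no studentized-range quantile). Multiplicity is controlled
by the Shaffer S1 step-down: at step i of the ascending p-values the
multiplier is the largest attainable number of true pairwise-equality
hypotheses ≤ m − i + 1, attainable counts coming from integer
partitions of the k species (a block of b equal means contributes
C(b,2) true hypotheses). Adjusted p-values are cummax-monotonized and
capped at 1; Shaffer ≤ Holm ≤ Bonferroni holds for every input (test
property). For k = 4 the multiplier sequence is (6, 3, 3, 3, 2, 1).

α = 0.05 for win calls (configurable). Species enter a category's model
only if present in ≥ 3 distinct subplots there (subplots, not
seedlings).

## Trade-off classification

Win/tie calls consume Shaffer-adjusted p-values within each
(category, metric) family; families are not pooled across categories.
Exact LS-mean ties (measure-zero in practice) are classified TIE so
pair-swap antisymmetry is unconditional. Undefined cells — species
excluded by the subplot rule — drop out of both numerator and
denominator of win proportions. The light-cross test uses the scheme's
high-TPAR cell for growth and low-TPAR cell for survival. Mean wins is
the unweighted average of the four per-metric proportions. No inference
is attempted on trade-off counts themselves: the six pairs from four
species are not independent.

## Relative importance (LMG)

Per species and RGR metric, y is regressed on initial height (always
first) plus five indicator blocks. The LMG share of block b is its
sequential R² increment averaged over all B! block orderings, computed
exactly via subset weights |S|!(B−|S|−1)!/B! — identical to explicit
enumeration (the test oracle enumerates). Shares are non-negative and
sum to total R² minus covariate-only R² to 10⁻¹⁰. Single-level blocks
are dropped with a warning; rank-deficient designs name the collinear
block. Normalized shares divide by the summed microhabitat shares
(×100); topography is the aspect + elevation + slope sum, and
species-averaged figures are unweighted means of per-species
percentages. Only Gaussian identity-link models are partitioned
(survival importance is out of scope). Treating initial height as a
competing sixth block instead of a forced-first covariate is possible
by passing it as a block; the forced-first reading matches "after
accounting for initial size" and is the default.

## Synthetic censuses and what they show

The generator mirrors the field design the analysis expects: 192 1 m²
subplots on a 16×12 grid, four species with abundances 1461/342/1402/49
(the strong imbalance of the motivating community), five censuses at
days 0/380/590/760/950, initial-height medians 0.9–4 cm. Growth is
simulated on the log-height scale — g = base + Σ habitat effects +
subplot intercept + seedling residual — so the two-point RGR estimator
is unbiased for the structural effects by construction, and the
downstream mixed model is correctly specified. Default SDs: σ_u = 0.05,
σ_e = 0.20 yr⁻¹ (growth); σ_u = 0.30 on the survival logit. Rounding to
0.5 cm is applied after simulation, so measurement attenuation is
quantifiable; survival is a per-interval draw from an annual logistic
hazard. Default species parameters build in opposite-sign
species×habitat growth effects and opposing growth/survival rankings,
so trade-off detectors have true positives at known locations; a null
configuration (identical species) supports false-positive calibration.

What passing these studies shows: the estimators are correct for the
model they assume, calibrated under the null, and powered for 3-σ rank
crossings. What they do not show: robustness to features of real
censuses the generator omits — non-constant individual growth,
density dependence, spatially clustered dispersal, substrate change
over a seedling's life, interval-censoring subtleties of mortality, or
model misspecification generally.

## Study sizes and numerical settings

Monte-Carlo studies use: 500 replicates for null calibration (band:
α ± 2 MC SE), 200 for rank-crossing power (≥ 95% detection), 200 each
for Gaussian/binomial Wald coverage (bands 90–98% / 88–98%), 100 for
LMG recovery (across-seed mean within 3 points of 57.1/28.6/14.3 —
the mean is the well-defined target since per-seed spread depends on
the chosen residual variance, set here so signal and noise variance are
equal), and 20/10 instances for the Gaussian/binomial oracle
comparisons (tolerances 10⁻⁶ / 10⁻³). Calibration cells use ~600
observations over 96 subplots with study-like species imbalance
(250/60/240/50). Convergence: REML scalar tolerance 10⁻¹⁰ on log λ;
Laplace inner Newton 10⁻¹⁰, outer BFGS gradient tolerance 10⁻⁷, ridge
10⁻⁴ under separation only. All simulation randomness flows from a
single seed through named `SeedSequence` streams, and pipeline outputs
are byte-identical for a fixed seed and configuration (timings are
logged to stderr only and never written into the output bundle).
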