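# Methods

This note documents the statistical models behind `qale_smallarea`, the
choices made where the methodology left room, and what the synthetic
validation does and does not establish.

## The estimand

Quality-adjusted life expectancy (QALE) at birth is a Sullivan-type
health expectancy: a period life table supplies the person-years lived
in each age interval (`Lx`), and a utility schedule — mean health
utility π(x) on the 0 (dead) to 1 (perfect health) scale — weights those
person-years:

    QALE(0) = (1 / l0) · Σ_x π(x) · Lx .

With π ≡ 1 this is ordinary period life expectancy; the package treats
that identity as a standing invariant (it is exercised by the test
suite and by the `pi_override` pipeline flag).

As a prevalence-based measure, the Sullivan method applies one
mortality schedule to everyone regardless of health state.  That is a
known limitation of the approach itself, accepted here deliberately;
incidence-based multistate methods are out of scope.

## Mortality: TOPALS

Small-area death counts by 5-year age group are too sparse to yield
stable single-age rates directly.  TOPALS (tool for projecting
age-specific rates using linear splines) regularises the problem by
modelling area log-mortality as a national reference schedule plus a
linear-spline offset:

    log m(x) = log m*(x) + Σ_k α_k B_k(x) ,

with hat-function bases B_k anchored at knot ages {0, 1, 10, 20, 40,
70, 100} — the convention of the reference TOPALS implementation, with
dense knots where the age pattern of mortality bends sharply.  The
offsets maximise a penalised Poisson likelihood for the grouped counts,

    Σ_g [ D_g log μ_g − μ_g ]  −  λ Σ_k (α_{k+1} − α_k)² ,

where μ_g aggregates expected deaths over the single ages of group g,
with group exposure split uniformly across its ages (single-age
populations are not observable in the grouped inputs).  Fitting is by
penalised iteratively reweighted least squares — Fisher scoring with
step halving — initialised at α = 0, converging when the gradient
2-norm falls below 1e-8 (max 100 iterations; non-convergence is flagged
on the result and warned about, never silent).

Choices worth knowing about:

* **Penalty weight λ = 1** by default, configurable.  The penalty is a
  stabiliser for sparse areas; at realistic death counts it is weak.
  Because λ does not scale with exposure, refits on fewer pooled years
  are very slightly smoother relative to the data — the effect is
  O(λ / deaths) and negligible outside of exact-invariance arguments.
* **Ages above the last knot** (100+) carry the last knot's offset
  (constant extrapolation); the basis itself refuses ages outside the
  knot span.
* **Identifiability**: a 5-year band provides one observation, so the
  two infant/child knots (ages 0 and 1), which sit inside the 0–4 band,
  are individually weakly identified at any exposure; the penalty
  resolves the ambiguity.  Consistency of the estimator is therefore
  checked on single-age inputs, where every knot is directly informed.
* **Old-age correction**: linear-spline tails can drift above age 90,
  so the fitted log-schedule is blended into an anchored reference:
  above `start_age` (default 90) the output is
  w(x)·[log m*(x) + offset(90)] + (1 − w(x))·log m_fit(x), with w
  rising linearly from 0 at 90 to 1 at the last age.  The area's level
  at 90 is kept; the reference shape takes over towards the oldest
  ages.  The exact correction used in the literature is not published
  in detail; this blend is this package's explicit choice, isolated in
  one function (`correct_old_age`) so it can be swapped.

## Life tables

Standard single-age period life tables closed at age 110.  Separation
factors: a0 = 0.07 + 1.7·m0 (capped at 0.5) for infancy, ax = 0.5
elsewhere, a = 1/m in the open interval, which is closed with
L = l/m and q = 1.  qx = mx / (1 + (1 − ax)·mx), capped at 1.  Radix
100 000, configurable; all rate- and expectancy-type columns are
invariant to it.

## Health: SF-12 to utility schedules

Survey microdata carry SF-12 Physical and Mental Component Summary
scores (PCS/MCS, T-scored: population mean ≈ 50, SD ≈ 10) and
cross-sectional weights.  The estimation is two-stage because raw cell
means are noisy and incomplete for small areas:

1. **Raw cell means.**  Weighted mean PCS and MCS per area × sex ×
   10-year age band; everyone aged ≤ 19 shares the 0–19 band (an adult
   panel has no child respondents, so this band is informed by ages
   16–19).  Empty cells are omitted, not imputed.
2. **Completion model.**  Weighted least squares of the cell means on
   sex, age band, sex × band, and an area fixed effect, weighted by
   cell respondent counts (equivalent to respondent-level fitting when
   weights are uniform within cells).  Predictions on the full
   rectangular grid fill in unobserved cells.  The design is built with
   deterministic dummy coding; rank deficiency beyond the dropped
   reference levels raises an error naming the aliased columns.
3. **Utility mapping.**  A deterministic quadratic in (PCS, MCS) with
   six named coefficients (intercept, PCS, MCS, PCS², MCS², PCS·MCS),
   clamped to [0, 1] by default.  Users who want a published
   SF-12-to-EQ-5D prediction model transcribe its coefficients into a
   `utility_mapping:` config block.  The shipped default is a
   **synthetic affine mapping** (0.1 + 0.007·PCS + 0.007·MCS), chosen
   so population-typical scores map to a utility of 0.8; it makes the
   package self-contained and — being linear — keeps the synthetic
   truth free of Jensen-gap bias.  It is not an estimate of any
   published mapping.

The sampling variance attached to each schedule entry is the raw
cell's within-cell variance of *mapped utilities* divided by its
respondent count: var_π = s²/n.  The plug-in (uncorrected) weighted
variance is used, so var_π scales exactly as s²/n under replication.
Cells with fewer than two respondents borrow the pooled (n-weighted)
within-cell variance of their sex × band, treated as a single
observation — a conservative fallback.

## Uncertainty of QALE

The variance of the Sullivan estimate is the sum of two independent
components.

**Health component.**  All single ages of a band share one estimated
utility mean, so their errors are perfectly correlated within band and
bands enter with squared person-year totals:

    var_health = (1/l0²) · Σ_b ( Σ_{x∈b} Lx )² · var_π(b) .

**Mortality component.**  Chiang-type binomial variances of the death
probabilities, Var(q_x) = q_x²(1 − q_x)/D_x, are propagated through the
utility-weighted expectancy by the delta method:

    ∂QALE/∂q_y = −(l_y/l0) · [ π_y (1 − a_y) + e'_{y+1} ] ,

where e' is the utility-weighted remaining expectancy, plus a Poisson
term for the open-interval rate, (π_w l_w / (l0 m_w))² / D_w.  Observed
grouped deaths are spread over single ages proportionally to fitted
expected deaths.  An age with zero observed deaths but death
probability strictly inside (0, 1) receives a continuity adjustment
(D := 0.5) with a logged warning.

Intervals are `point ± z·SE` with z the central-normal quantile:
1.282 at the default 80% level, 1.960 at 95%.  The 80% default trades
interval width against usefulness for small areas, where 95% intervals
are often too wide to rank anything.

**Calibration caveat.**  The health variance deliberately uses the raw
cell's s²/n even though π itself comes from the completion model.  The
model pools information across cells (the area effect is estimated from
all of an area's cells), so its predictions are less variable than raw
cell means and the resulting intervals are conservative: on synthetic
replicates under this package's study conditions the 80% intervals
cover the true QALE at roughly 85–89%.  The conservatism is a property
of the raw-cell variance convention, which is retained because it is
the standard practice for Sullivan-type health expectancies and is
robust to model misspecification that the model-based alternative would
hide.

## Reporting and the inclusive-economy association

Descriptive reports: population-weighted national means (weights are
total area population, shared by both sexes), within-nation ranges with
the extreme areas named, and within-area female-minus-male gaps in LE
and QALE, flagging reversal areas (female survival advantage without a
female health advantage — the health-survival paradox pattern).

The exploratory association analysis regresses area QALE (years) on
all 13 inclusive-economy indicators jointly, one OLS model per sex.
Indicators are z-standardised (mean 0, sample SD 1, n−1 denominator),
so each coefficient is years of QALE per 1 SD of the indicator;
directions are taken exactly as supplied and never flipped.
Per-coefficient 95% CIs come from the t distribution; the summary
statistic is adjusted R² = 1 − (1 − R²)(n − 1)/(n − p − 1).  At least
p + 2 = 15 areas are required; near-collinearity (condition number
above 1e8) warns with diagnostics rather than failing.

## The synthetic system

The generator emulates the statistical structure of the pipeline's four
inputs, with a truth file (never read by estimation code) for recovery
tests.

* **Reference mortality**: a Siler curve (exponentially declining
  infant mortality + background + Gompertz senescence) with parameters
  set so national life expectancy is ≈ 79.6 (M) / 83.2 (F) years, and a
  +0.08 log-shift for Scotland; Wales +0.02.
* **Areas**: defaults describe district-scale areas — populations
  uniform on [25 000, 250 000], allocated across the three nations
  proportionally to their local-authority counts, with a shared smooth
  stable-population age shape (reference survivorship discounted at
  0.4% growth), which isolates mortality and utility effects from
  compositional ones.
* **Mortality truth**: per area × sex, spline offsets at the TOPALS
  knots, α ~ offset_sd · (ρ·h + √(1−ρ²)·ε), with h the area's latent
  health level and ρ = −0.5 by default (healthier areas have lower
  mortality).  Because the truth is exactly spline-shaped, recovery
  tests measure estimation error, not model misspecification.
* **Deaths**: Poisson draws per area × sex × 5-year band × calendar
  year around the truth-implied expectation; three pooled years
  (2018–2020) by default, the last carrying a 13% rate shock emulating
  pandemic-scale excess mortality, which gives the sensitivity switch
  something real to find.  Populations can optionally be rounded to
  100s, emulating disclosure control in published estimates.
* **Survey**: respondents aged 16–89 drawn from the population shape;
  PCS declines ≈ 1.1 points/decade with age and MCS rises slightly, a
  male-female offset on both, ±2 score points per SD of latent health;
  within-cell noise SD 10 (the T-score scale); log-normal weights with
  mean 1.  Per-area sample sizes are uniform on [30, 400] — the
  published per-area sample-size distribution of the real panel is not
  known, so it is exposed as configuration rather than fixed.
* **Indicators**: each of the 13 indicators is its published mean plus
  its published SD times (effect·h + noise), with signed default
  effects following the indicator set's direction conventions;
  percentages clipped to [0, 100], ratios kept positive.
* **Truth QALE** uses the same banded step schedule and the same
  (affine) mapping as the estimator, with band truth defined over the
  band's surveyed age range — so estimator and truth target the same
  quantity and recovery error is attributable to sampling noise.

What the synthetic validation does **not** establish: robustness to
non-spline-shaped true mortality, to informative non-response or
area-varying sampling design in the survey, to mis-specified utility
mappings, or to population denominators biased between censuses.  All
of these affect real applications.

## Problem sizes used in validation

Monte-Carlo calibration runs 500 replicates of a 40-area system (80
area-sex estimates each) in the test suite and 300 replicates in the
acceptance script; association recovery uses 500 replicates of 40
areas; the TOPALS oracle comparison uses 20 random grouped instances
and consistency uses single-age exposures of 1e7.  These sizes give
Monte-Carlo standard errors well below the decision thresholds they
feed (e.g. ≈ 0.6 percentage points for a coverage proportion at 500 ×
80 estimates).
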