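# Methods

This note documents the models and procedures `healthineq` implements, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical conventions used throughout.

## Fractional ranks

All indices are driven by the weighted fractional income rank. With persons
sorted by household income per capita (stable sort, poorest first), person
*i*'s rank is `R_i = (cumulative weight before i + w_i/2) / W`. Under equal
weights and distinct incomes this is exactly `(i − 0.5)/n`. Two conventions
are fixed here and asserted by tests:

- **Ranking unit.** Persons, not households, are ranked; every person
  carries their household's income per capita. A household's members
  therefore tie by construction.
- **Ties.** Tied incomes share the weighted midpoint rank of their tie
  block. Survey income has mass points, and the strict-ordering formula
  would make the index depend on the arbitrary within-tie row order; the
  mid-rank makes every downstream statistic tie-order invariant. The
  weighted mean rank is exactly 0.5 for every input (the algebraic identity
  `Σ w_i (cum_i + w_i/2) = W²/2` holds block-wise), which the index formulas
  rely on; tests assert it to 1e-12.
- **Missing income** is refused, not imputed. Imputation policy belongs to
  the caller, not to a rank routine that cannot know the survey's design.

## Concentration indices

The standard index is computed in covariance form, `C = 2 cov_w(h, R)/h̄`,
which equals the weighted direct sum `Σ (w_i/W)(h_i/h̄)(2R_i − 1)` because
the weighted mean rank is 0.5. Weights enter the mean, the covariance and
the ranks symmetrically, so equal weights reproduce the unweighted textbook
formula exactly (asserted to 1e-10 against an independently coded direct
sum).

The Erreygers correction is computed as `E = 8 cov_w(h, R)/(h_max − h_min)`
— algebraically identical to `4h̄C/(h_max − h_min)` but numerically stable
when `h̄` is tiny, and manifestly invariant to level shifts (the covariance
ignores constants). Bounds default to (0, 1); non-binary outcomes must
declare bounds explicitly. The Wagstaff normalisation
`W = (h_max − h_min) h̄ C / ((h_max − h̄)(h̄ − h_min))` is undefined when the
mean sits at a bound and raises rather than returning infinity. The binary
identity `E = 4h̄(1 − h̄)W` is asserted to 1e-12.

The concentration curve is built over income tie blocks (cumulative weight
share vs cumulative outcome share). For a piecewise-linear curve on these
points, the trapezoid rule makes `1 − Σ Δx (y_k + y_{k−1})` *exactly* the
grouped-data concentration index, so the curve/area identity holds to
floating-point error; the test tolerance of 1e-6 is generous.

## Uncertainty

The interval machinery is a design choice: applied work in this field
typically prints 95% CIs without fully specifying the estimator, and the two
standard options are both provided so they can be compared.

- **Convenient regression (default).** WLS of the transformed outcome
  `2σ²_R h_i/h̄` (scaled per variant) on `R_i` with the survey weights; the
  slope reproduces the direct formula to 1e-10 (asserted at run time) and
  its heteroskedasticity-robust (HC1) or cluster-robust standard error gives
  a normal-theory CI. Ranks are treated as fixed, the standard convention
  for this estimator.
- **Clustered percentile bootstrap.** Whole clusters (PSUs when available)
  are resampled with replacement; ranks are recomputed inside every
  resample, so rank-estimation variability is captured. Degenerate
  resamples (index undefined, e.g. an all-zero outcome) are redrawn with a
  logged count and a cap of 10× the requested replicates. Percentile
  intervals are clamped to contain the point estimate. Validation: over 200
  simulated surveys of n = 2,000 with a known index of 0.2, the 95% interval
  from 500 clustered resamples covers the truth 94–96% of the time.

Significance stars (\*p < 0.1, \*\*p < 0.05, \*\*\*p < 0.01) come from the
two-sided test of index = 0 using the same SE as the CI. Classification is
interval-based: pro-rich iff the whole CI is above zero, pro-poor iff below,
indeterminate otherwise.

## Probit decomposition

A weighted probit (`statsmodels` GLM, binomial family, probit link,
`var_weights`) links the binary outcome to the covariate design. The model
is linearised with partial effects `β_j^m`:

- continuous covariates: the survey-weighted mean of `β_j φ(η_i)`;
- binary covariates: the per-observation discrete 0→1 change in the fitted
  probability, averaged **over the subgroup that holds the attribute**
  (e.g. the effect of female sex is the mean effect among women). This
  subgroup rule captures that attribute-holders differ from the population
  in their other characteristics. The conventional everyone-averaged AME is
  computed and stored alongside, and `decompose(averaging="overall")`
  switches to it, since practice varies on this point.

Contributions are `4 β_j^m GC(x_j)` with `GC(x) = 2 cov_w(x, R)` (the
covariance form is valid for covariates of any sign). The **residual is
defined by closure** — `E(h) − Σ contributions` — so additivity holds to
machine precision on every input; the independently computed `4·GC(e)` of
the linear-approximation error is reported as a diagnostic. The two agree
identically in exact arithmetic (`E(h) = 8cov(β₀ + Σβx + e, R)` expands
term by term), and to ~1e-8 in floating point on realistic designs.

Shares are contribution/E(h) and may legitimately exceed 100% or be negative
when contributions offset. When `|E(h)|` falls below a configurable floor
(default 0.01) shares are suppressed — the division is numerically
meaningless near zero — while raw contributions remain available.
Categorical covariates expand to indicators against a named reference level;
the study pipeline adds weighted income-quintile indicators (reference:
poorest) as the socioeconomic-status factor and region indicators as fixed
effects, both configurable. Rank-deficient designs and perfect separation
are rejected with the offending covariate named, never silently fitted.

## Synthetic survey generator

The generator emulates the statistical structure of a national household
health survey so that the full pipeline can be exercised with known truth:

- **Income**: log-normal per region (σ = 0.9) with region-specific location
  shifts (poorer North/North-East, richer South-East/South); five regions
  with population shares roughly matching Brazil's. Log-normality is a
  modelling choice: it gives the needed right skew with two parameters.
- **Weights**: gamma with mean 1 (shape 4) by default, to exercise weighted
  estimators without replicating a real three-stage design; `uniform` gives
  equal weights for analytic checks.
- **Households**: sizes uniform on a configurable range; members share
  income, weight and region. Stratum ids are region × weighted income
  tercile; PSU ids are blocks of 25 households within a stratum. These
  exist solely so clustered-bootstrap code paths have realistic structure.
- **Covariates** declare an Andersen role and a dependence on the income
  *rank* (logistic for binary, linear for continuous). Specifying
  dependence on the rank rather than raw income keeps closed-form index
  expectations tractable.
- **Outcomes** follow a probit latent model over covariates and optionally
  the rank, a probability *linear in the rank* (`p = a + bR`, for which the
  Erreygers index has the closed form `2b/3`, since `E = 8b·Var(R)` and the
  weighted rank distribution is uniform with variance 1/12), or a constant.
  Probabilities escaping [0, 1] are an error — never clipped, because
  clipping would silently change the model the truth object claims.
- **Eligibility** (e.g. mammogram: women 50–69) is encoded as not-applicable
  markers, not dropped rows, so the pipeline's filter step is a real,
  testable operation. A configurable fraction of positive hospitalisation
  cases among women 18–49 is flagged delivery-only for the recode rule.
- **Randomness**: one deterministic stream per component (households,
  demographics, weights, each covariate, each outcome), derived from the
  config seed, so adding a covariate does not perturb incomes. Fixed seed ⇒
  bit-identical tables.

What the generator does **not** emulate: within-household outcome
correlation beyond shared income and region (persons are independent given
covariates), non-response and calibration weighting, the real three-stage
sampling design, item missingness, or longitudinal linkage across waves.
Passing tests therefore demonstrate correctness of the estimators under a
clean data-generating process, not robustness to the messiness of real
survey data.

## Study pipeline conventions

- The analysis sample is adults (18+) for every outcome; screening outcomes
  additionally restrict to their sex/age windows (Pap smear: women 25–59;
  mammogram: women 50–69). Delivery-only admissions are recoded to
  non-use and stay in the denominator. Filter logs conserve counts
  (`rows_in = retained + excluded`) by construction.
- **Regional indices re-rank within the region.** A region's index is
  interpreted as within-region inequality, so a region-constant outcome has
  a regional index of zero however poor the region is nationally (tested).
  National ranking for regional cells would be a different estimand.
- Prevalence uses the weighted mean with the design-based normal
  approximation SE `sqrt(Σ w_i²(h_i − p)²)/W`; the clustered bootstrap is
  available through the same CI machinery when preferred.
- Declarative row filters in the config (column/op/value) support
  exclusions such as dropping rural areas of one region for cross-wave
  comparability, rather than hard-coding any particular rule.
- Everything is deterministic given the config seed; per-wave, per-outcome,
  per-region bootstrap seeds are derived via `numpy.random.SeedSequence`.
  Two runs of the same config render byte-identical report files (tested).
- A stratum with no eligible rows, or a degenerate index within a stratum,
  becomes an empty cell with a logged diagnostic; it never aborts the study.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` use n = 100,000 × 20 seeds for
the analytic-recovery check (Monte-Carlo error ≪ the ±0.02 band),
n = 20,000 × 50 replicates for driver recovery, and n = 2,000 × 200
surveys × 500 resamples for bootstrap coverage — sizes at which the checked
quantities are stable while the whole validation completes in about a
minute on one CPU.

## Known limitations

- Convenient-regression SEs condition on the estimated ranks; the bootstrap
  is the remedy when rank variability matters.
- The decomposition is descriptive, not causal: contributions quantify
  association patterns under a linear approximation of a probit fit.
- The Wagstaff variant is undefined at degenerate prevalence (0% or 100%),
  and near-zero total indices make shares unstable (hence the share floor).
- No multiplicity adjustment is applied across outcomes or regions; each
  cell's stars are marginal.
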