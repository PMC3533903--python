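# Methods

## Model

The measurement model is the Partial Credit Model (PCM). For item j with
maximal code `m_j` and step thresholds `δ_j1..δ_jm_j`,

    P(Y_nj = y | θ_n) = exp(yθ_n − Σ_{l≤y} δ_jl) / Σ_c exp(cθ_n − Σ_{l≤c} δ_jl),

the empty sum applying at y = 0. All probability evaluations subtract the
row maximum before exponentiating and are stable for |θ| ≤ 40. An item's
*location* is the mean of its thresholds, a one-number difficulty summary.

The structural model is a latent regression with heteroscedastic variance:

    θ_n ~ N(μ_n, σ²_n),   μ_n = μ* + X_n β,   σ²_n = σ²* + Z_n γ,

where μ* and σ²* are the mean and variance of the reference group (all design
columns zero) and X, Z are person-level designs built from treatment-coded
factors, grouped-level indicators (e.g. one column for "North or West"),
quantitative recoded age, and order-2 interactions. The variance uses the
identity link as written; a fit whose variance model reaches the positivity
floor (10⁻³) is flagged invalid together with the offending covariate
pattern rather than silently truncated.

## Estimation

**Pairwise conditional estimation (PCE).** For each unordered item pair and
each person observing both, the probability of the observed pair given its
sum is free of θ. The summed negative log conditional likelihood is convex
in the cumulated thresholds and is minimized by L-BFGS with an analytic
gradient (observed indicator sums minus conditional tail expectations).
Exactly one direction is unidentified — adding a constant to *every*
threshold — so a quadratic penalty on the total sum pins it during
optimization and the solution is centered to Σδ = 0 afterwards. Item pairs
with no joint observations are dropped with a warning; categories observed by
nobody are collapsed downward, warned about, and the old→new code mapping is
returned. Pairs are not reweighted beyond their data (each person-pair
contributes once).

**Calibration (marginal ML).** Thresholds and σ² are estimated jointly with
θ ~ N(0, σ²) — μ fixed at 0 for identifiability — by Gauss–Hermite
quadrature (21 nodes by default), starting from the PCE solution, with
analytic gradients built from posterior node weights. Calibrated thresholds
are then frozen for every latent-regression fit.

**Latent regression.** The marginal likelihood Π_n ∫ Π_j P(Y_nj|θ)
φ(θ; μ_n, σ²_n) dθ is evaluated with Gauss–Hermite nodes centered at μ_n and
scaled by σ_n for each person (21 nodes; doubling the order moves the
log-likelihood by < 10⁻⁴ on the test scenarios, which the suite asserts).
Gradients are exact (posterior-weighted score residuals chained through μ_n
and σ_n); standard errors come from a central finite difference of that
gradient (observed information), and p-values are Wald. AIC = 2k − 2logL
with k counting only the free structural parameters of the fit.

**Backward elimination.** Mean-model terms are selected first (variance model
empty), then variance terms with the mean model held. Each round removes the
largest-p removable term with p ≥ 0.05 whose removal does not increase AIC,
refitting warm-started from the current optimum; interactions are removable
before their main effects, and a main effect is locked while any retained
interaction involves its variable. Trial fits skip the information matrix;
it is recomputed on acceptance.

## DIF scan

Stage 1 fits one PCE model per stratum of the declared factors (the survey
design gives gender × 7 age bands × 2 years = 28 strata; strata under 30
persons are dropped with a warning). Item locations are analysed by a
weighted least-squares main-effects ANOVA (weights = stratum sizes) with
per-factor F tests; the *large DIF* flag requires p < 0.05 **and** a spread
of weighted factor-level mean locations above 0.1 logits. Flagged factors
have their levels merged greedily — walking levels in order (or by mean
location for unordered factors) and closing a group when its location spread
would exceed 0.1; a collapse to a single group rescinds the flag. Stage 2
re-runs the scan on region × year strata after pseudo-item expansion of
stage-1 DIF items; a split item's stratum location is the observation-count
weighted mean of its pseudo-item locations.

Because each stratum model is identified only up to the sum-zero constraint,
a large shift on one item leaks a small opposite shift (−shift·m_j/Σm) into
the other items' locations; the no-DIF error-rate guarantees therefore apply
to data without true DIF, and secondary flags near a strong genuine DIF
should be read with that in mind.

## Nonparametric checks

Loevinger's H_jk is the ratio of the observed inter-item covariance to the
maximum attainable under the same margins, computed on pairwise-complete
cases via the comonotone (sorted) coupling; H_j and H aggregate numerators
and denominators. Zero-variance items make their pairs undefined and are
reported as such. Monotonicity uses listwise-complete rest scores, merged
into groups of at least N/10 (capped at 500) persons; every ordered pair of
rest-score groups is compared for each item step, a decrease beyond 0.03
counting as a violation with a two-proportion z statistic. The composite is
the MSP-style criterion

    Crit = 50(0.30 − H_j) + √#vi + 100·#vi/#ac + 100·maxvi + 10·√Σvi
           + 1000·Σvi/#ac + 5·max z + 10·√Σz + 100·Σz/#ac,

reported raw (it is negative when there is no violation and H_j > 0.30);
values below 40 are acceptable. The numeric value is documented here rather
than claimed to match any particular legacy implementation.

## Item-trait fit test

For each item, persons are ordered into up to 10 near-equal class intervals
and observed scores are compared with model-expected scores. The
conditioning is deliberately *leave-one-out*: for item j the posterior uses
only the other items, the expected score and its variance are posterior
moments given that rest, and the grouping key is the rest-posterior mean.
Given the rest of a response vector the observed item score then has exactly
the computed conditional mean, so each interval's standardized sum is
asymptotically N(0,1) and the per-item statistic is χ² with one degree of
freedom per interval (df = J·G in total). Two implementation details matter:
intervals need at least 20 persons (fewer intervals are formed otherwise,
and the test is reported undefined below two), and the grouping key is
quantized to 9 decimals so that persons with identical rest patterns tie
exactly — the float residue of computing the rest likelihood by subtraction
depends on the person's own response, and letting it break sort ties would
bias the interval sums. Under the null this construction holds the 5%
rejection rate within binomial tolerance (asserted over 500 replicates at
N = 2000 in the suite).

The large-sample rescaling multiplies the statistic by N₀/N (N₀ = 500 by
default) and recomputes the p-value at unchanged df; below N₀ the statistic
is returned unchanged with a note.

## Explained variance and age recoding

τ = 1 − [(n−1−k)σ̂²] / [(n−1−k₀)σ̂₀²] compares the calibrated latent variance
(no covariates, k₀ parameters including thresholds) with the homoscedastic
fit carrying the selected mean terms (k parameters). The pipeline computes
the with-covariate σ̂² from exactly that homoscedastic refit so the
comparison matches the definition.

Age recoding divides fitted age-band dummy coefficients by the
smallest-magnitude nonzero coefficient and then searches multipliers 1..6
for the smallest under which every score sits within 0.25 of an integer
(half-unit patterns double cleanly); the result must be nonnegative and
nondecreasing, with an optional pool-adjacent-violators projection for
non-monotone patterns. Whether the recoding is retained is an AIC comparison
against the dummy fit, done at the pipeline level.

## Synthetic data

The generator draws independent factors with configurable frequencies
(defaults mirror the French survey structure: gender 46.5/53.5, seven age
bands, the nine-region distribution 21/10/8/15/7/11/8/9/11%, survey years in
the 13.9/86.1 ratio), a trait from the heteroscedastic structural model
(configurations with non-positive variance are rejected), PCM responses —
with per-(item, factor level) threshold shifts for true DIF, implemented as
an equal shift of all the item's thresholds — and missingness that is MCAR
or trait-informative (logistic in −θ with the intercept calibrated to a
target overall rate). Item banks default to five 4-category items with
locations spread over ±1 and steps at location ±1. Everything is
deterministic under a seed.

What the generator does **not** emulate: correlated covariates (an option
exists but the default is independence, unlike real surveys), multidimensional
traits, non-uniform DIF (slope differences), survey weights, and item-specific
wording effects. Passing tests therefore demonstrate correctness of the
estimators under the stated model, not robustness to those violations.

## Problem sizes and numerical choices

The simulation-based checks run at desk scale: threshold recovery at
N = 2000 over 20 replicates; coefficient recovery at N = 5000 over 50
replicates with thresholds frozen at their generating values (so the check
isolates the structural estimator; calibration accuracy is asserted
separately); DIF error rates over 200 replicates of a 12-stratum design and
power over 100 replicates with 3000 persons per stratum; fit-test
calibration over 500 replicates at N = 2000. Optimizations use L-BFGS-B
with ftol 10⁻¹¹ and analytic gradients throughout; quadrature defaults to
21 nodes (61 for EAP person estimates, which are cheap).

## Known limitations

* Identity-link variance models can reach the positivity boundary for
  extreme covariate patterns; the fit is flagged rather than repaired (a
  log-link alternative is a natural extension).
* The ANOVA on stratum locations treats estimated locations as observations,
  inheriting the approximate inferential frame of that design; p-values are
  F-based.
* Per-factor pseudo-item expansion duplicates the responses of an item split
  on two factors (one copy per factor); the cross-product switch avoids this
  at the cost of smaller groups. The response-multiset invariant holds only
  for single-factor splits.
* Backward elimination explores a single greedy path; it is not an exhaustive
  model search.
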