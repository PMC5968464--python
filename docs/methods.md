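# Methods

This note records the models, assumptions, numerical conventions and open
design choices behind `itemcount`, in the spirit of a statistical package's
methods appendix. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## 1. The list-experiment model

A survey instrument consists of `B` blocks; each block holds one sensitive
true/false statement and `J` non-sensitive control statements (`J = 4` in
the default five-block instrument). Respondents are randomized — with
probability 0.60, stratified by truth stratum — to **Arm A**, which hears
all `J + 1` statements and reports only the count of true ones (the
sensitive item's position within the block uniformly randomized over
`1..J+1`), or to **Arm B**, which answers every statement individually,
the sensitive one after the controls.

Identification of the sensitive prevalence by the difference in means
rests on three assumptions:

1. **Arm exchangeability** — randomization makes the arms comparable, so
   the control-answer distribution is the same in both arms.
2. **No design effects** — a respondent's control answers are not changed
   by the presence of the sensitive item in the list.
3. **Truthful counting** — the count equals the number of statements the
   respondent holds true (no misreporting, no miscount).

The package's purpose is largely to quantify what happens when assumption
3 fails, and to detect failures of assumption 2.

The validation context this package targets is a population with linked
surveillance records: four truth strata — HIV-positive linked to HIV care
(status known to the individual), HIV-positive unlinked, HIV-negative, and
surveillance-test refusers — so that elicited estimates can be compared
against researcher-known truth at the individual level. Truth is
stratum-determined for two items ("I am HIV negative", "I refused the
HIV test"); the remaining items (tooth brushing — the tutorial block —
condom use, anal sex) have configurable prevalences.

## 2. Response model of the synthetic cohort generator

`generate_cohort(n, design, config)` draws, per respondent:

* **stratum** ~ Categorical(`stratum_props`, default 0.25 each, emulating
  a stratified target sample drawn equally from the four categories);
* **arm** ~ Bernoulli(`arm_allocation` = 0.60) independently of stratum
  and truth (stratified randomization);
* **truthful answers**: stratum-determined where applicable; refusers'
  unobservable HIV status is imputed Bernoulli(`pop_neg_prev` = 0.31, a
  population-prevalence figure for the kind of high-prevalence setting
  the design targets), which keeps individual-level truth defined for
  every respondent while reproducing the population-level adjustment
  downstream; all control items Bernoulli(their design probabilities),
  independent of everything else (the independence the instrument design
  assumes);
* **misreporting**: an answer to a *sensitive* item whose truthful value
  is socially undesirable (true under a −1 item, false under a +1 item)
  flips to the desirable answer with probability `lambda_direct` when
  asked directly and `lambda_list` when contributed to a count. Control
  items, being non-sensitive, are never misreported. Setting
  `lambda_list < lambda_direct` encodes the concealment hypothesis; the
  generator deliberately allows every ordering, since whether list
  formats actually reduce misreporting is exactly what validation studies
  ask.
* **miscount**: the Arm A count suffers a ±1 slip (direction fair) with
  probability `epsilon_count`, clamped to `[0, J+1]` — the simplest model
  of finger-counting error.

No quantitative misreporting rates are established for such settings; the
defaults are all 0 (noiseless), and scenario values such as
`lambda_direct = 0.3` are exploration settings, not estimates. The
generator does **not** model household/geographic structure, interviewer
effects, item-order effects other than the recorded sensitive position,
correlated control answers, or refusal-to-participate processes — so
passing recovery tests demonstrate internal consistency of the estimators
under the stated response model, not robustness to those real-data
features.

For regression experiments, `item_prevs` accepts
`(intercept, {covariate: slope})` linear-probability specs over generated
covariates (clipped to [0, 1]).

Determinism: one `numpy.random.Generator` is spawned per cohort from a
root `SeedSequence`; all sampling is vectorized over respondents in a
fixed order, so a seed fully determines the cohort byte-for-byte, and
replicate studies spawn independent child streams per cohort.

## 3. Estimators and uncertainty conventions

* All intervals are Wald intervals with the conventional 1.96 multiplier,
  matching the symmetric intervals validation studies print. Proportion
  intervals are truncated to [0, 1]; the LR difference is not.
* The difference in means uses unpooled (Welch-style) variances: the two
  arms' outcomes are constructed differently (counts of `J+1` items vs
  sums of `J`), so equal variances are not assumed.
* The adjusted-truth estimator `(n_true,tested + p0·n_refused)/n_total`
  reuses the non-refused subsample's CI half-width unchanged — an
  explicitly conservative choice treating the population imputation as
  adding no precision. With zero refusers it reduces exactly to the
  unadjusted estimator (tested).
* The list regression stacks the Arm A count and Arm B control sum into
  one outcome and fits OLS on covariates plus arm-indicator interactions
  (via `statsmodels`); interaction coefficients (`delta`) form the
  sensitive-item submodel, main effects (`gamma`) the control-sum
  submodel. Heteroskedasticity-robust HC2 errors are reported, since the
  interaction model is heteroskedastic by construction. The linear form
  is chosen for computational robustness; maximum-likelihood list
  estimators (which can fail to converge at validation-study sample
  sizes) are deliberately out of scope.
* `residual_se` is reported as RMSE divided by the outcome's standard
  deviation: a dimensionless fit index, 0 for a perfect fit and ≈ 1 for a
  model with no explanatory power. Rows with missing covariates are
  dropped and the per-arm n reported.
* Intercept-only regression equals the difference in means exactly (an
  algebraic identity of interaction least squares); the test suite checks
  it to machine precision, which also guards the two code paths against
  each other.

## 4. Diagnostics

**Design-effects nonnegativity test.** With `F_A`, `F_B` the empirical
CDFs of Arm A counts and Arm B control sums (plain proportions ≤ y, no
smoothing — exactness over elegance),

```
pi(y, 1) = F_B(y) − F_A(y)        y = 0..J
pi(y, 0) = F_A(y) − F_B(y−1),     F_B(−1) := 0
```

are the proportions of respondent types (y affirmative controls,
sensitive answer z). They telescope to exactly 1. Cell variances add the
two arms' independent binomial CDF variances. Each negative cell gets a
one-sided z-test against zero; the reported p-value is
`min(1, m · min_i p_i)` over the `m` negative cells (Bonferroni over the
*negative* cells only — the operative test; correcting over all
`2(J+1)` cells would only make an already-conservative boundary test more
conservative), and 1 when no cell is negative. The normal approximation
makes small-sample p-values approximate; the suite verifies the test is
conservative (null rejections ≤ nominal 5%) rather than exactly sized.

**Position effects.** The LR estimate is recomputed with Arm A restricted
to each sensitive-item position (Arm B, which has no positions, enters
every stratum). Heterogeneity across positions is tested with a
Cochran-style chi-square on the per-position Arm A mean counts weighted
by `1/Var(mean)`. The shared Arm B mean cancels in every between-position
contrast, so including the control-arm variance in the weights would
double-count common noise and distort the null distribution; the
statistic therefore uses the Arm A means alone, is asymptotically
χ²(k−1) under position-independence, and its p-values are verified
approximately uniform under the null. Positions with fewer than two Arm A
respondents are reported unavailable and excluded from the statistic.

**Floor/ceiling profile.** The empirical Arm B control-sum distribution
per block; mass at 0 or at J measures how often a count would reveal the
sensitive answer.

**Balance.** Welch two-sample t-tests per field across arms; degenerate
zero-variance comparisons are assigned p = 1 (equal means) or p = 0.

## 5. Block assignment

Under item independence the block count is Poisson-binomial; its pmf is
computed by exact convolution of the `J+1` Bernoulli two-point
distributions, and the extreme-count (leakage) probability is
`pmf[0] + pmf[J+1]`. `search_assignment` reproduces the
design-by-simulation workflow: random partitions of the control pool into
blocks, each scored by the sum (optionally max — the aggregation is a
genuinely open choice; sum is the default because it is the expected
number of leaking blocks per respondent) of per-block extreme
probabilities, argmin kept, ties resolved to the earliest candidate so a
seed determines the answer. The exact oracle is the default scorer;
Monte-Carlo scoring is retained for fidelity to the simulation workflow
and an exhaustive mode covers small pools. Only the `{0, J+1}` extremes
are penalized; near-extreme counts are not.

The default instrument's control-item probabilities are **placeholders**
(plausible everyday-behaviour rates); the assumed probabilities used to
design any real instrument are population-specific and should be supplied
via the item-pool input.

## 6. Data interchange

Canonical respondent tables are wide CSV (UTF-8, header row): one row per
respondent; Arm A rows carry `count_block{b}`/`pos_block{b}`, Arm B rows
`ctrl_b{b}_i{k}`/`direct_b{b}`; booleans as 0/1, missing as empty string.
Validation is strict by default (row-indexed messages; arm exclusivity,
range and stratum/truth-consistency rules), with an opt-in lenient mode
that drops offending rows and reports them, and read/write round-trips
are exact. External files are ingested only through an explicit
`ColumnMapping` (renames + value recodes); unknown headers are never
guessed. A published validation dataset can be analysed this way, but
whether a given deposit retains truth strata and item-level answers after
de-identification varies; operations whose required fields are absent
fail with a message naming the field (estimates are marked unavailable,
never silently zero).

One documented discrepancy is surfaced rather than resolved: in the
validation study this package is patterned on, the stated refuser
adjustment applied to the published counts (≈22% of 483 tested negative,
~72 refusers, 31% population prevalence) yields ≈26.6%, matching the
study's "26%" population-truth figure, while the study elsewhere prints
an adjusted estimate of ~32%. The implementation follows the stated
formula; the worked-counts unit test pins `(106 + 0.31·72)/483`.

## 7. Problem sizes and tolerances

Replicate studies in the tests and acceptance script use 200 cohorts of
n = 2000 for estimator-recovery properties, 500 cohorts of n = 400 for
design-effects null calibration, and 200 cohorts of n = 1500 for
position-test uniformity — sizes at which Monte-Carlo standard errors are
small enough to separate real bias from noise while the whole suite runs
on a laptop in well under a minute. Stochastic assertions use 3
Monte-Carlo-standard-error bands (≈99.7% coverage per check); exact
identities (convolution vs enumeration, regression identity, CDF
telescoping) are asserted at 1e-9–1e-12 absolute tolerance.

## 8. Known limitations

* Wald intervals can undercover for proportions near 0/1 at small n; the
  package mirrors the analysis convention of its domain rather than
  switching to Wilson/Agresti-Coull intervals.
* The design-effects test has limited power at validation-study sample
  sizes (a few hundred respondents); a non-rejection is weak evidence of
  absence.
* The misreporting model is marginal per item; it does not model
  respondents whose misreporting is correlated across items or driven by
  the elicitation format itself beyond the `lambda_list`/`lambda_direct`
  split.
* Estimates are never reweighted to a sampling frame; the package targets
  internal-validity comparisons (LR vs direct vs truth on the same
  sample), not population-representative prevalence.
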