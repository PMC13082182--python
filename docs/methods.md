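# Methods

This note documents the statistical models implemented in `hrphase`,
the choices made where the design was genuinely open, and what the
synthetic validation does and does not establish.

## Heart-rate phase

**Model.** Weekly profile bins (5-min, Sunday-origin time-of-week; at
most 2016 bins) are fit by unweighted least squares to
`HR(t) = A sin(pi/720 (t - 60*phi_h)) + b` with the period fixed at
1440 min. The problem is linear in `(a, c, b)` with basis
`{sin wt, cos wt, 1}`; the canonical parameters are `A = sqrt(a^2+c^2)`
and `phi = wrap(atan2(-c, a) * 720/pi)/60` hours. There is no
iterative optimisation and hence no initialisation sensitivity; the
test suite confirms equality (to 1e-6) with a Levenberg–Marquardt fit
of the nonlinear parameterisation and with an exhaustive grid-search
oracle over phase.

**Phase convention.** `phi` in hours, `[0, 24)`, is the *ascending
mean-crossing* time of the sinusoid. The heart-rate peak (acrophase in
cosinor terminology) occurs at `phi + 6 h`. All downstream effects
("per hour of HRP") are on this scale.

**Aggregation choices.** Samples are floored to their containing
5-minute bin; the bin value is the mean over all of the participant's
dates. Fitting uses the full 2016-point weekly series, not a collapsed
288-point daily profile, and bins are unweighted regardless of how many
samples they contain — the two differ only when bin occupancy is
unequal, and the weekly unweighted series is the more literal reading
of the aggregation description. Timestamps are naive local time; no
timezone or daylight-saving handling is attempted.

**Degenerate inputs.** Fewer than 3 bins with distinct time-of-day, a
constant profile (`SS_tot = 0`, reported as `R^2 = 0`), or a singular
design are flagged rather than raised; flagged fits carry `R^2 = 0`
and are removed by the goodness-of-fit filter.

**Threshold selection.** Retention at threshold θ is the number of
participants with `R^2 > θ` divided by the number with `R^2 > 0`;
the Youden-type index `retention(θ) + θ - 1` is maximised over the grid
`{0.0, 0.1, ..., 0.9}` (step configurable), ties broken toward the
lowest threshold. With high-quality data the index rises with θ and
selects a high cutoff; a real-cohort convention of 0.5 is available by
passing the threshold explicitly.

**Inclusion filters**, applied in order: (1) strictly more than 30
distinct calendar dates with data; (2) `R^2` strictly above the
threshold; (3) on the survivors, phases at or beyond 3 SD from the mean
are excluded. The mean and SD in (3) are linear (not circular), in
hours, computed once without iteration — appropriate because the phase
distribution is treated as unimodal for continuous analysis; with zero
SD nothing is excluded. Step (3) uses the population SD (`ddof=0`).

## Genotype–phase association

Allele frequencies are computed on whatever genotype table is supplied
(the base population size is recorded); the reference allele is the
most frequent, the alternate the second most frequent, and variants
with alternate AF < 1% are excluded. Dosage is the additive count of
alternate alleles; calls containing any other allele exclude that
participant from that variant only. The association model is OLS of
phase (hours) on dosage, age, Y-chromosome presence and PC1–5 with
heteroskedasticity-consistent standard errors (HC1 by default,
configurable HC0–HC3), effects reported in minutes per allele, and
Bonferroni adjustment over the number of variants actually tested in
the run — never a hard-coded count.

## PheWAS

The condition vocabulary is a directed acyclic graph (tree or DAG);
closure uses shortest-path distance, so a concept's cases are the
participants with an occurrence of the concept or any descendant within
two degrees. Concepts with **strictly more than** 100 cases are
retained (100 exactly is dropped). Each retained concept gets a
logistic regression of case status on phase, weekly steps, age at
study end, Y-chromosome presence and PC1–5 with HC1 errors, Bonferroni
over the retained-concept count. Non-convergent or separated fits are
flagged in the output table, never silently dropped. Focused disease
definitions (T2DM) use the same machinery at unlimited depth.

## Diabetes outcomes

HbA1c measurements must lie in [1, 30]% (inclusive); the analysis value
is each participant's maximum strictly **before** the end of wearable
monitoring (date-equal measurements excluded — the conservative
reading), elevated means strictly > 5.6%, and participants with no
qualifying measurement are excluded from HbA1c models. The age
covariate in HbA1c models is age at the end of monitoring; elsewhere
it is the lesser of age at death and age at study end. The "linearity
of log-odds" check is an empirical-logit-by-decile table
(`empirical_logit_by_decile`) rather than by-eye visualisation.

Cox regression runs on the age scale, stratified by Y-chromosome
presence, with weekly steps and PC1–5 as covariates and right-censoring
at the lesser of age at death and study end. No left truncation at
monitoring start is applied (delayed entry is not part of the
specification this follows); this is a known deviation risk if
participants enter observation late, and the post-monitoring subgroup
analysis (first diagnosis after monitoring initiation) is the provided
robustness probe. Proportional hazards are checked by the
scaled-Schoenfeld test and reported alongside the fit.

Two-group comparisons use Welch's t (normal scale) or Mann–Whitney U,
with Cohen's d on the pooled-SD definition and a 95% CI from the
normal-approximation standard error of d (as in `pingouin`); zero
variance in both groups is flagged and, when the means also agree,
reported as d = 0.

## Mendelian randomization (2SRI)

Stage 1: OLS of phase on instrument dosage and the exogenous
covariates (steps, age, sex, PC1–5); instrument strength is the Wald F
of the dosage coefficient (F < 10 raises a weak-instrument warning, not
a failure) together with the stage-1 R². Stage 2: logistic regression
of the outcome on the stage-1 residual, phase and the same exogenous
covariates. The causal estimand is the stage-2 phase coefficient; the
residual coefficient is reported as an endogeneity diagnostic.

Confidence intervals: participants are resampled with replacement and
*both stages re-fit* inside each replicate — the standard one-sample
choice; percentile intervals are reported (no CI-type refinement such
as BCa), along with both the analytic robust-z p-value and a bootstrap
sign-flip p-value, since which of the two a published figure reflects
is often unstated. Non-convergent replicates (typically separation in
small resamples) are dropped and counted. The reference configuration
uses 100,000 resamples; validation experiments use 1,000, which is
sufficient for percentile endpoints at the reported precision.
Bootstrap replicates use a plain Newton/IRLS logistic solver that
agrees with the reference MLE to 1e-8 (unit-tested) but skips the
covariance computation that the replicates do not need; headline fits
always go through `statsmodels`.

## Synthetic cohort

The generator emulates the five input tables with the causal structure
the analyses assume:

- phase: `phi_i = mu + sum_v dosage_iv * effect_v/60 + c*U_i + N(0, sd)`
  with `U_i ~ N(0,1)` an unobserved confounder and `c` the confounding
  strength (default 0);
- heart rate: the sine model plus Gaussian noise on a 5-min grid over
  `n_days`, bins dropped independently with the missingness rate;
- disease: Bernoulli with logit
  `intercept + effects(phase, steps, age, sex) + c*U_i`, covariates
  centred at their generative means so the intercept is the null-model
  log-odds;
- diagnosis ages: for cases, onset-age-20 exponential waiting times
  with rate proportional to `exp(covariate effects)`, truncated at the
  censoring age — higher risk is stochastically earlier, and the
  condition table places each occurrence uniformly within the
  concept's descendant closure so the closure logic is exercised;
- HbA1c: Gaussian with a linear phase slope, a 40% sampled fraction,
  and a 2% out-of-range artifact rate so the [1, 30] filter has work
  to do (values are deliberately not clipped into range);
- genotypes: Hardy–Weinberg draws per variant with a small third-allele
  rate to exercise the non-biallelic exclusion.

Because the logistic case indicator and the diagnosis-age model share a
linear predictor, the joint process is *not* an exact proportional
hazards law; Cox recovery is therefore validated against a dedicated
generator (`simulate_survival_cohort`) whose truth is exactly
exponential-PH, right-censored at the age at study end.

**Default conditions.** Phase mean 9.48 h and SD 1.57 h; T2DM log-OR
ln(1.09) per hour; Y-chromosome prevalence 0.32; an rs1144566-like
morningness variant at AF 0.025 with −30 min/allele; HbA1c sampled for
40% of participants. Amplitude (10 ± 3 bpm), baseline (72 ± 8 bpm),
sampling noise (5 bpm), weekly steps (5.5 ± 2 × 10⁴) and age (55 ± 12 y)
are chosen as physiologically plausible for an adult wearable cohort;
resting-HR circadian amplitudes of 5–15 bpm and 1–2 h phase SDs are
typical of actigraphy-scale studies. Amplitude is generated
independently of phase, since no dependence is specified anywhere.

**MR demonstration conditions** (`mr_demo_config`): confounding at unit
loading (`c = 1`), instrument −30 min/allele at AF 0.20, causal log-OR
0.1/h. The unit loading matters: with weak confounding the naive
estimator's bias is smaller than the 2SRI sampling error and a
bias-comparison experiment would be uninformative; with unit loading
the naive bias (~0.25 on the log-odds scale) is several 2SRI standard
errors, so the comparison discriminates.

**What passing tests show — and don't.** The synthetic streams are a
single stationary sinusoid plus white noise with missing-completely-
at-random gaps. Real wearables data have ultradian structure, activity
artefacts, informative missingness (device off during sleep or
charging), day-of-week and seasonal nonstationarity, and phase that
drifts within participants. Recovery under the synthetic conditions
validates the estimators' correctness, not the robustness of HRP to
those violations; the inclusion filters (days, fit quality, outliers)
are the only defence implemented here.

## Validation problem sizes

Chosen so every experiment has meaningful power: phase recovery at 200
participants × 60 days (σ = 5 bpm, 20% missingness); logistic CI
coverage at 100 replicates of n = 15,000; PheWAS family-wise error at
100 replicates of 200 null concepts, n = 2,000; Cox recovery at
n = 10,000 (~1,700 events); MR bias comparison at 50 replicates of
n = 15,000 and bootstrap coverage at 200 replicates of n = 1,000 with
1,000 resamples each. Determinism is checked by hashing the full run
manifest of two identically-seeded end-to-end runs.

## Known limitations

- Single-harmonic fixed-period model; no period estimation or
  multi-component cosinor.
- Linear (non-circular) statistics on phase throughout, valid only for
  unimodal phase distributions away from the wrap point.
- No left truncation in the Cox model (see above); no competing risks;
  no medication adjustment in the HbA1c pathway.
- Single-instrument MR; no pleiotropy sensitivity analyses (MR-Egger,
  weighted median) and no two-sample machinery.
- The 2SRI estimand for a logistic stage 2 is conditional on the
  residual proxy of the confounder; under strong unmeasured
  confounding it remains approximately, not exactly, unbiased for the
  conditional causal log-odds ratio.
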