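# Methods

## The metric

For one participant, index their 3-minute training tasks by *i* and let
RT_i be the mean reaction time within task *i* (seconds) and Accuracy_i
the proportion of correct trials.  The digital biomarker is the pooled
product-moment correlation

    RTACC = corr(RT_i, Accuracy_i),

computed over all tasks of all games and sessions in a stated time window
(default: the full 24 weeks; sensitivity windows use weeks ≤ W for
W ∈ {1, 2, 3, 6, 12, 24}, inclusive).  Pairs are pooled rather than
averaged per game: the definition indexes tasks, not games, and pooling
uses all information in one estimate.  A value is reported as undefined
(rather than raising) when fewer than `min_pairs = 10` pairs remain after
selection or when either series is constant; undefined values are dropped,
with a logged count, before modelling.  Pearson is the default reading of
"correlation" for a mean/proportion pair; a Spearman option exists for
robustness checks.  Leave-one-game-out variants recompute the correlation
on the complement of each of the 18 catalogue games.

## Preprocessing

Ingested training logs are schema-checked; rows violating record
invariants (non-positive RT, accuracy outside [0, 1], week < 1,
unparseable numerics) are quarantined to a reject table with line numbers,
never silently dropped.  Missing RT/accuracy cells are counted and
excluded (no imputation).  Outliers are flagged by the scaled-MAD rule:
flag v iff |v − median| > k · 1.4826 · MAD with k = 3, applied per
participant and separately to the RT and accuracy series; a record flagged
on either is removed.  Per-participant application avoids conflating
between-person speed differences with outliers; a pooled-cohort mode is
available behind a flag.  When MAD = 0 (near-constant series) nothing is
flagged and a warning is emitted — under a degenerate scale every deviant
would otherwise be removed, discarding valid near-constant performers.
Participants with fewer than 3 records are skipped from flagging and
noted.

## Synthetic cohort generator

The generator emulates the data structure of a 24-week multi-domain
intervention trial in MCI; it is the package's test bed, and its defaults
are the study conditions every simulation-based check runs under.

**Participants (n = 130).**  Age ~ N(73.02, 5.53²) truncated to the
[60, 85] eligibility window; education years ~ N(10.73, 4.54²) truncated
to [0, 22]; sex ~ Bernoulli(0.6385) with 1 = female; APOE ε4 carriage
~ Bernoulli(0.3154); baseline RBANS ~ N(90.10, 15.26²), untruncated.

**Coupling.**  Each participant carries a latent coupling
ρ_p ~ N(−0.10, 0.20²) truncated to (−1, 1).  The observed distribution of
the correlation metric is not published; these two numbers are calibration
choices, fixed so that the planted outcome effect reproduces the published
effect size and standard error (below) at n = 130 with ~390 pairs.

**Training stream.**  Per week, sessions ~ Uniform{3, 4, 5}, four
3-minute tasks per session, games cycled over the 18-game catalogue —
24 × 4 × 4 = 384 expected pairs per participant (~390, closed form
available as `CohortConfig.expected_pairs_per_participant`).  Each task
draws a bivariate standard-normal latent with correlation ρ_p; the RT
latent maps through a lognormal transform (location 2.5 s, log-scale
σ = 0.15, floor 0.2 s) and the accuracy latent through a linear link
(mean 0.75, SD 0.08) clipped to [0, 1].  Both latents are clipped at
±2.0 SD: a 3-minute task score is an average over 10–30 trials, so gross
single-task outliers do not occur, and default streams pass the k = 3 MAD
screen untouched.  With σ = 0.15 the lognormal attenuation of the Pearson
correlation is below 1%, and the measured planted-coupling bias including
the clip is ≤ 0.007 across ρ_p ∈ [−0.6, 0.3].

**Difficulty staircase.**  Level (1–10, starting at 1) increments after a
task with accuracy ≥ 0.85, decrements below 0.65, clamped to bounds.  By
default the level does not shift the performance distributions: adaptive
difficulty exists to hold effective challenge constant, so a stationary
stream is the intended emulation — and it keeps the population RT–accuracy
correlation exactly at the planted ρ_p.  Per-level RT/accuracy slopes are
exposed as knobs (`rt.level_slope`, `accuracy.level_slope`); setting them
non-zero engages a sequential simulation in which difficulty feeds back
into performance (and the marginal correlation then deviates from ρ_p by
construction).

**Outcomes.**  On the change scale,

    ΔRBANS = b0 + b1·age + b2·sex + b3·education + b4·APOEε4
             + b5·baseline + b6·ρ_p + Σ_m c_m·Δmarker_m + ε,

with defaults b6 = −11.90 (the published adjusted effect), b5 = −0.12
(regression to the mean), modest covariate effects (b1 = −0.15, b2 = 1.0,
b3 = 0.2, b4 = −2.0), b0 = 26.68 chosen so the mean change is 8.26, and
ε ~ N(0, 8.0²) chosen so the change SD is ≈ 8.74 and the RTACC
coefficient's standard error is ≈ 3.5–3.8 at n = 130.  Each biomarker
change is a_m + β_m·ρ_p + ε_m with β_m the published path coefficients
(BDNF −3.132, pTau 2.832, NfL 3.879, GFAP −31.69) and residual SDs
back-solved from the published path standard errors; the marker→outcome
weights c_m default to 0, mirroring the non-significant published paths,
and are configurable for power studies.  Residual SDs of 0 are allowed to
switch noise off for exactness checks.

**Determinism.**  All randomness flows from one seed through named
substreams (participants / per-participant training / outcomes /
bootstrap), so a fixed config reproduces every artifact bit-for-bit, and
a participant's stream is reproducible in isolation.

### What the generator does not emulate

No dropout or attrition (the analysis set is complete-case), no
trial-level key-press simulation by default, no learning curves or
practice effects (the stream is stationary), no within-week session
structure beyond counts, and no missing data (matching the source trial's
report).  Passing tests therefore show that the estimators recover known
truth under a well-specified, light-tailed generative model — not that
real training logs satisfy these assumptions.

## Models

**Adjusted regression.**  OLS of week-24 RBANS on intercept, age, sex,
education, APOE ε4, baseline RBANS, and RTACC; classical SEs and two-sided
t p-values.  Regressing the week-24 score with baseline as a covariate is
used rather than the change score — identical except for the baseline
coefficient (shifted by 1).  Rank-deficient designs raise an error naming
a collinear term.

**Robust variant.**  Huber M-estimation via IRLS (tuning 1.345, ≈95%
Gaussian efficiency), scale re-estimated each iteration as the normalized
MAD of residuals, convergence on coefficient change at 1e-8 within 50
iterations; non-convergence returns the fit flagged `converged = False`
with a warning.  As tuning → ∞ the fit equals OLS exactly.

**Path system.**  Observed-variable recursive system: each marker change
regressed on RTACC, and the outcome on RTACC plus all marker changes;
equation-wise least squares is ML for a recursive system with uncorrelated
errors.  The outcome equation adjusts for the regression covariates and
baseline by default (the published adjusted and path-model direct effects
are nearly identical, suggesting the original analysis adjusted); the flag
`adjust_covariates=False` switches to unadjusted change-score equations.
Indirect effects are, definitionally, the product of the two path
estimates.  Pruning is backward elimination over the marker paths (both
RTACC→marker and marker→outcome): repeatedly drop the single largest-p
path with p ≥ α (default 0.05) and refit; the direct path is never
dropped, and the full removal trace is recorded for audit.  Note that
threshold-based elimination retains the *smallest* of several null
p-values when it happens to fall under α, so with 8 null paths a spurious
marker path survives in roughly a fifth of replicates — an intrinsic
property of stepwise selection at α = 0.05, visible in the simulation
tests.

**Responder models.**  Good responder ⇔ RBANS increased at week 24; poor
⇔ decreased; exact ties form a third label excluded from fits.  Three
logistic models (clinical covariates / RTACC only / both) by ML; in-sample
predicted probabilities scored by the rank (Mann–Whitney) AUC, ties
counted ½ — identical to trapezoidal ROC integration.  95% CIs by seeded
stratified percentile bootstrap (2000 resamples within each class).  No
cross-validation by default, matching the apparent original procedure;
in-sample AUCs of fitted models are optimistic, which is why the null
simulations use the single-predictor model.  Complete separation is
detected, flagged, and the fit falls back to a weakly regularized
estimate rather than aborting.

## Numerical choices

Correlations are computed by the centered sum formula with a roundoff
guard: exact-constant series are declared undefined before centering, and
results are clamped to [−1, 1] against last-ulp excursions.  Degenerate
MAD → flag nothing + warn.  The analysis table is complete-case over the
regression terms; the path model is additionally complete-case over the
requested markers.  CSV artifacts carry the config hash as a leading
comment line (readers skip `#`); JSON artifacts embed it as a field; the
output directory is excluded from the hash so identical analyses in
different locations compare equal.

## Simulation sizes

The recovery and type-I simulations use 1000 replicate cohorts at full
study size (n = 130, ~384 pairs per participant); coupling recovery uses
200 replicate streams per value; contamination-robustness and pruning
simulations use 200 replicates; oracle-equivalence checks use 100–1000
random instances.  These sizes give Monte-Carlo standard errors well below
the tolerances they are checked against (e.g. ±0.7% on a 95% coverage
estimate at 1000 replicates).

## Known limitations

RTACC inherits Pearson's sensitivity to the marginal distributions of RT
and accuracy; the Spearman option is a partial mitigation.  The planted
linear outcome model cannot probe non-linear coupling–outcome
relationships.  In-sample AUCs overstate out-of-sample discrimination.
The staircase's default decoupling from performance means difficulty
trajectories carry no information in synthetic data, so analyses of the
difficulty column itself should enable the level-slope knobs.  The Huber
estimator bounds, but does not nullify, gross-outlier influence; when
contamination-induced error is comparable to sampling error its per-replicate
advantage over OLS is modest (see the robustness simulation).
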