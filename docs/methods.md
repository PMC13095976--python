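# Methods

## The task and its analysis model

One trial of the force-matching task: squeeze a dynamometer so the force
stays inside a band of ±5% (multiplicative) around a target drawn from
{20, 40, 60, 80, 100}% of the squeezing hand's MVC, accumulating 3 s inside
the band within a 7 s window; then rate perceived effort on a 0–100 scale
anchored at "no effort" and "effort of the MVC measurement". Hands
alternate strictly; each hand performs four repetitions per submaximal
level and three at 100% MVC, giving 2 × (4·4 + 3) = 38 trials. The hold
criterion is **cumulative** time in band by default (a `consecutive_hold`
flag switches to the longest-run rule; both are scored by
`determine_outcome`).

The analysis is two-stage. First level, per participant:

    rating_t = β0 + β_F · f_t² + β_X · failure_t + β_H · hand_t + ε_t

fit by a Huber M-estimator (IRLS; tuning constant 1.345 for 95% Gaussian
efficiency, ≤50 iterations, coefficient tolerance 1e-8, MAD scale). β_F is
the participant's force sensitivity, β_X their failure sensitivity. The
squared force enters because the quadratic link wins the model comparison
(below); `actual_force_sensitivity` repeats the fit with the transformed
area under the force curve replacing target force. A participant whose
outcome column is single-class is rank-deficient in this design and is
excluded upstream rather than fitted.

Second level: each sensitivity is regressed on PHQ9, AES, sex, age and the
MVC ratio. Continuous variables (including the outcomes) are z-scored with
the population SD — this makes coefficients standardised and exactly
invariant under sample replication — and the four symptom coefficients
(PHQ9/AES × force/failure) form one Benjamini–Hochberg family.

## Link-function selection

Eight linear mixed models of rating on transformed force plus hand: four
transforms × {random intercept, random intercept + random slope on the
transform}, all by full maximum likelihood (not REML, so models differing
in fixed effects remain BIC-comparable), with
BIC = k·ln N − 2·ln L, k = 3 fixed effects + 1 or 3 random-effect
(co)variances + 1 residual variance, N = trials. Ratings are divided by 100
before fitting purely to stabilise the optimiser; the divisor is constant
across the grid so BIC differences are unaffected. `lbfgs` can report a
spurious boundary optimum with infinite likelihood on the intercept-only
cells, so fits fall through bfgs → powell → nm and accept the first finite,
converged result. Ties break toward the simpler random-effects structure,
then the transform order listed below.

The transforms are parameter-free so each model stays linear in its
coefficients: identity `f`, quadratic `f²`, hyperbolic `f/(1+f)`, and
exponential `exp(2f) − 1`. The exponential rate deserves a note: with
`exp(f) − 1` the exponential column is >99% collinear with `f²` over the
task's force range (f ≈ 0.2–1.3), and the four-way comparison degenerates —
any small concave contamination of the observed curve (rating-ceiling
clipping, the failure-rate term) decides the winner by noise. `exp(2f) − 1`
keeps the family distinctly more convex than the quadratic, which restores
an identifiable comparison and reproduces the qualitative goodness-of-fit
ordering this design produces (quadratic best, hyperbolic worst,
exponential between). Because the transforms and the force normalisation
are package choices, absolute BIC values are not comparable across
implementations; only the ordering is meaningful.

## The MVC miscalibration and exclusions

The task software scaled targets by the *opposite* hand's MVC: a trial
logged at nominal fraction x was experienced at e = x · MVC_opp / MVC_own
of the squeezing hand's own MVC. `correct_target_forces` maps logged to
experienced fractions (dominant × MVC_nondom/MVC_dom, nondominant the
reciprocal); `apply_miscalibration` is its exact functional inverse
(round-trip error < 1e-12). Inside the generator the bug is physical:
traces, outcomes and ratings are driven by e while the trial table logs x.

Exclusion cascade, on the corrected cohort:

1. **Top-quartile MVC ratio** — the ⌊n/4⌋ largest dominant/nondominant
   ratios are removed (108 → 81 when n = 108); ties at the boundary break
   by stable participant-id order and are noted in the report.
2. **Data quality** — cohort mean ± 2.5 SD bounds on (a) each participant's
   Spearman ρ between corrected force and rating and (b) failure
   proportion, both computed on the same post-quartile snapshot; plus
   exclusion of zero-variance outcomes. Since regressions run on the
   lag-complete trials (the first trial drops for its undefined lag
   features), the single-class check is evaluated on that subset, and it is
   applied in both directions (all-success *and* all-failure) because
   either is rank-deficient. An SD of zero disables the corresponding
   criterion rather than excluding everyone.

Re-running the data-quality step on its own output removes no one on the
simulated cohorts used in the tests; the quartile rule, by construction,
always removes a quarter and is therefore not idempotent.

## Trace features

All features use forces as fractions of the correct hand's MVC. Area under
the curve is the trapezoidal integral over the trial window; the
coefficient of variation uses the sample SD (ddof = 1) over the mean of the
full recorded trace; the initial peak is the first local maximum of height
≥ 0.1 (fraction-of-MVC units) via `scipy.signal.find_peaks`, falling back
to the global maximum with a flag on monotone traces; excess force is
AUC − target × 3 s; cumulative force sums AUCs through the current trial
inclusive. Lag features take the previous trial's rating and target; the
first trial is dropped rather than imputed. Flags (undefined CV, peak
fallback) propagate with the matrix.

## Huber-weighted cross-validated ridge

Per participant, features and outcome are z-scored within participant
(fits are per-person and betas compared across people), a Huber fit of
rating on all features yields final IRLS weights in (0, 1], and a weighted
ridge — solved exactly via one eigendecomposition of ZᵀWZ per fold for the
whole path — is cross-validated over 50 log-spaced λ ∈ [1e-3, 1e3] with
10 seeded shuffled folds. Validation MSE is weighted by the same trial
weights by default (they encode trial reliability, not fold membership); an
unweighted flag exists. The smallest λ attaining the minimum mean
validation MSE is kept and coefficients are refit on all rows. Group
summaries are across-participant means with t-based 95% CIs; feature
correlation matrices are averaged elementwise across participants, with a
participant's constant feature contributing missing entries that drop from
the mean.

## The synthetic cohort generator

The generator is the package's testbed: it emulates the statistical
structure the analyses assume, with every generative parameter recorded in
`sim_*` columns.

**Force traces.** A linear ramp (0.7 s) to the intended level
min(e, capacity), an overshoot transient (Gaussian bump at the ramp end,
per-trial amplitude ~ N(0.10, 0.07) of the level), and
Ornstein–Uhlenbeck-style motor noise (correlation time 0.4 s) low-passed at
0.08 s — muscle force is rate-limited, so recorded traces are smooth at the
sample level — with stationary SD = motor_noise_scale · level^1.5. The
supra-linear exponent makes the ±5% *relative* band progressively harder to
hold, producing failure rates that rise from ≈25% at 20% MVC to ≈90% at
100% MVC (cohort mean ≈ two-thirds) under the default
motor_noise_scale = 0.13 (log-normal across participants, σ_log = 0.35).
`capacity` ~ N(1.0, 0.05) caps sustainable force near the measured MVC.
After the success criterion is met the grip releases with a 0.25 s decay
(disable with `release_after_success=False`), which decouples excess force
from target force. In the noise-free limit (motor_noise_scale = 0,
overshoot terms 0) the trace holds the target exactly after the ramp.

**Ratings.** rating = clip(β0 + β_F e² + β_X failure + feature terms +
N(0, 7), 0, 100), with the feature terms computed by the same feature code
the analysis uses: overshoot × (−15), cumulative force × 0.05, CV × 4,
excess × 1.5, lag terms 0 by default. Defaults were chosen so the
*observed* phenomenology matches the study conditions jointly: mean ratings
rise ≈ 20 → 90 across levels with limited ceiling pile-up, the quadratic
link wins the BIC comparison, overshoot has a detectable negative and
fatigue a positive group effect.

**Individuals.** β_F ~ 60 + 15·(ρ_F·z + √(1−ρ_F²)·ε) with latent symptom
trait z ~ N(0,1), default ρ_F = −0.5; β_X ~ 5 + 8·(+0.5·z + …);
intercept ~ 10 + 6·(0.33·z + …). PHQ9 discretises 6.41 + 4.03·z clipped to
[0, 27]; AES discretises an independent trait (31.41 + 6.82·z', [18, 72]) —
only rank/linear association matters downstream. Demographics: age
~ N(27.7, 5.8) in [18, 45], P(female) = 62/108, P(right-handed) = 98/108,
MVC ~ log-normal (median 320 N, σ_log = 0.25), dominant/nondominant ratio
log-normal (median 1.07, σ_log = 0.09).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: learning or serial drift beyond cumulative
fatigue, rating anchoring dynamics and round-number preferences,
correlated PHQ9/AES traits, EMG-level trace structure, or any systematic
hand asymmetry beyond the MVC difference. Recovery results demonstrate the
*pipeline* is consistent, not that real effects take these values.

## Problem sizes and numerical choices

Monte-Carlo studies (link recovery: 20 cohorts × 40 participants; coupling
recovery: 20 × 100; null false-positive control: 200 × 100; failure curve:
200 trials/level) simulate traces at 50 Hz, a five-fold downsampling of the
250 Hz acquisition rate; the rate only discretises time-in-band scoring and
feature integrals, and the task's dynamics live well below 25 Hz. Unit
tests and the default pipeline use 250 Hz. All randomness flows through
`numpy` `SeedSequence` spawning, so every schedule, trace, cohort and CV
fold split is reproducible from a single seed; derived seeds stay below
2³¹. In the null study, "findings" are counted per q-value (fraction of
the 4 × 200 symptom tests with q ≤ 0.05), the stable quantity under FDR
control; the per-replicate any-rejection rate of Benjamini–Hochberg under
the global null equals α by construction and is therefore not a usable
calibration check.

## Known limitations

- The exponential/hyperbolic transform forms are package conventions;
  other choices change absolute BICs (and could change close orderings).
- The Huber tuning constant, λ grid and fold count are sensible defaults,
  not tuned to any dataset.
- Second-level inference is classical normal-theory OLS on z-scored
  variables; no robust standard errors at level 2.
- The generator's rating model is additive with Gaussian noise and a hard
  clip; real visual-analogue ratings are heteroscedastic and lumpy.
- With 38 trials per participant the first-level failure slope is
  estimated with substantial noise; group-level couplings attenuate
  accordingly (visible in the recovery study's error distribution).
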