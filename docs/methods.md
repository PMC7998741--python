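# Methods

This document records the measurement model, the statistical procedures, the
synthetic-data generator and the numerical choices made in `pabcog`. The
package targets a cross-sectional design comparing physical-activity behavior
(PAB) and executive function across four vocational-education tracks
(Hairdresser, Admin, Sports, Nursing; default group sizes 26/24/34/19).

## 1. Accelerometry (`pabcog.accelerometry`)

**Input.** A posture-event table: `participant_id`, `start` timestamp,
`duration_s`, `activity` ∈ {sitting, standing, stepping, time_in_bed},
`steps`. Events of one participant must be contiguous and non-overlapping
(tolerance 1 ms, to absorb microsecond-precision serialization) and strictly
positive in duration; violations raise `StreamValidationError` naming the
offending pair.

**Day splitting.** Events are cut at local midnight; durations and steps are
pro-rated by the fraction falling on each side. A day is *complete* when its
events cover 86 400 s within 1 ms. A participant is *valid* with ≥ 2 complete
weekdays and ≥ 2 complete weekend days; only complete days of valid
participants enter group statistics.

**Sedentary bouts and SB-ratio.** A bout is a maximal run of consecutive
sitting events; any other class, including time in bed, terminates it. The
SB-ratio is sedentary time accrued in bouts strictly shorter than the cut-off
(default 30 min; a bout of exactly 30 min is a long bout) divided by total
sedentary time, `NaN` when there is no sedentary time. Pooled computation
(default) classifies each bout by its full length even when it straddles
midnight, attributing time to days pro rata; `sb_ratio_per_day=True` instead
averages per-day ratios.

**MVPA.** Stepping events with cadence = steps/duration ≥ 100 steps/min count
toward moderate-to-vigorous activity. Cadence is evaluated per event (the
generator emits homogeneous-cadence events); `cadence_window_s` optionally
re-evaluates over fixed windows. Youth guideline: ≥ 60 MVPA min on *every*
complete day. Adult guideline: mean daily MVPA × 7 ≥ 150 min. Adherence is
`None` when the participant is invalid.

## 2. Cognition (`pabcog.cognition`)

**CST filter chain**, applied in this fixed order to the 5 × 64 test trials:

1. *Chance filter*: ≤ 32 of 64 correct in any round excludes the whole
   participant (all 320 trials logged as `chance_excluded`).
2. Round-3 non-shift trials dropped (the first trial of a switching round is
   by construction not a shift).
3. Round-4/5 congruent trials dropped.
4. RT window: trials with RT < 170 ms or > 5000 ms dropped; the boundary
   values are retained.
5. Incorrect trials dropped.
6. Per-round mean ± 3 SD screen, a *single pass* computed on the survivors of
   steps 2–5 (no iteration until convergence; `sd_pooled_rounds=True` pools
   rounds 1–2 and 4–5 instead).

Every removal is attributed to exactly one rule, so the exclusion log
balances: input = survivors + Σ removals.

**Scores.** Shifting cost = mean RT of surviving round-3 shift trials −
pooled mean of surviving round-1/2 trials (option: mean of round means).
Inhibition cost = pooled round-4/5 incongruent mean − the same baseline.
Missing components are `NaN` with a recorded reason, not an error. The LMT
updating score matches the recalled multiset against the last three presented
letters per trial (order-free; duplicated targets must be recalled the right
number of times), summed over ≤ 12 trials (range 0–36). The chance filter is
a CST rule; the LMT score stands on its own session.

## 3. Statistics (`pabcog.stats`)

**ANCOVA.** Manual design matrix: intercept, k−1 treatment dummies
(alphabetical reference level), covariates; listwise deletion (counted);
zero-variance covariates are dropped so the model degenerates exactly to
one-way ANOVA. The omnibus group F is the extra-sum-of-squares test of the
full model against the covariates-only model (equivalent to the Type-III
group test in this main-effects model), df = (k−1, n−k−p). EMMs are model
predictions at the covariate grand means with SE = σ̂·√(x'(X'X)⁻¹x), using
the Moore–Penrose pseudoinverse for numerical safety. Pairwise contrasts are
Bonferroni-adjusted over all k(k−1)/2 pairs. Cohen's d for a pair is
(EMMᵃ−EMMᵇ)/s_pooled with group SDs reconstructed as SE·√n and (n−1)-weighted
pooling; the 95% CI uses SE_d = √((nₐ+n_b)/(nₐn_b) + d²/(2(nₐ+n_b−2))).
Significance tiers: p < .05 significant, p < .10 borderline.

**Collinearity screen.** VIFs from least-squares R² of each covariate on the
others (∞ under exact collinearity); covariates with VIF > 10 are flagged. Of
the deliberately collinear fat %/muscle % pair the pipeline keeps fat %, the
study's adjustment variable.

**Adherence.** Pearson chi-square on the 2 × k adherent/non-adherent table
without continuity correction; post-hoc cell inspection via adjusted
standardized residuals z = (O−E)/√(E(1−row/n)(1−col/n)) with Bonferroni
correction over k columns.

**Associations.** For each of the 3 × 3 (sitting, standing, stepping) ×
(inhibition, shifting, updating) cells: Pearson, Spearman and Kendall tau-b
coefficients with p-values on pairwise-complete cases; per-outcome OLS
regressions; subset sensitivity re-analysis (subsets below 10 complete cases
are skipped with a warning) reporting sign and significance agreement.

**Power.** Power of the one-way omnibus F from the noncentral F distribution
with λ = f²·N; `anova_power_n` returns the smallest N reaching the target
power. By default it searches balanced designs (N a multiple of k, the
G*Power a-priori convention), giving N = 76 for k = 4, f = 0.40, α = .05,
power = .80; `equal_groups=False` searches every integer total and yields 73
for the same inputs.

## 4. Synthetic generator (`pabcog.synthdata`)

**Scope.** The generator exists to validate the pipeline: it produces data
that satisfy the measurement model exactly, with known ground truth, unbiased
class means and reproducible streams. It is not a behavioral simulation of
real adolescents; bout structure, cadence and RT distributions are simple
parametric stand-ins.

**Daily composition.** Each track profile fixes target daily hours for the
four classes summing to exactly 24 (validated at construction). Participant-
and day-level Gaussian offsets are projected to zero sum with
variance-proportional weights, so rows still sum to exactly 24 and class
means remain unbiased for the targets. Draws violating positivity are
redrawn (up to 200 attempts; degenerate zero-variance profiles short-circuit).
Default between-participant SDs: sitting 1.5, standing 1.1, stepping 0.6,
time in bed 0.95 h.

**Event streams.** One nightly in-bed episode straddles midnight (fraction
before midnight ~ N(0.88, 0.04) clipped); waking time is tiled with
exponential-length bouts (mean per class from the profile, minimum 1 s)
rescaled to hit the day's class totals exactly, interleaved so the same class
never repeats consecutively unless forced. Stepping cadence mixes a brisk
component (105–125 steps/min, profile `mvpa_fraction` of stepping time) with
a strolling component (70–95). Sub-microsecond residual events are dropped;
the final event is nudged so the stream closes the full span exactly.

**Cognitive sessions.** RTs are lognormal with mean-parameterised location
(μ = log m − σ²/2, cv default 0.2, base 600 ms, shift +250 ms, incongruent
+120 ms); contamination by fast guesses (U(50, 169.9) ms) and lapses
(U(5000.1, 9000) ms) at configurable rates; accuracy 1 − error rate. LMT
recalls are correct with probability 0.75 by default; wrong recalls are drawn
outside the target multiset so they can never score.

**Reproducibility.** All randomness flows from `numpy` `SeedSequence`s
spawned per participant; no global state is touched. Identical configs
reproduce byte-identical CSV/JSON artifacts (enforced by a test).

**Defaults.** Track daily-hour targets are plausible occupational profiles
(e.g. Hairdresser 7.65 sit / 5.14 stand / 1.72 step / 9.50 bed,
proportionally rescaled to sum to 24); sitting-bout means 18/19/15/18
min for Hairdresser/Admin/Sports/Nursing; MVPA fractions 0.42/0.38/0.48/0.42;
covariate distributions include a deliberate fat %/muscle % correlation of
−0.9 to exercise the VIF screen. Cognitive ground truth is shared across
tracks (a null configuration), so any PAB–cognition association in generated
data is a false positive — the property the calibration test exploits.

## 5. Numerical choices and limitations

* Durations are kept in float seconds; conservation checks use 1 µs
  tolerances, stream contiguity 1 ms (absorbing CSV timestamp rounding).
* The SD screen is deliberately single-pass; iterating to convergence would
  remove more trials and change scores.
* Pseudoinverse-based ANCOVA tolerates rank deficiency instead of erroring;
  exact collinearity among covariates should be caught upstream by the VIF
  screen.
* The chi-square has no continuity correction and is unreliable for the very
  small expected counts typical of low adherence; the package reports it as
  specified but the post-hoc residuals should be read with that caveat.
* Emergent quantities of the generator (e.g. the SB-ratio implied by
  exponential bout tiling after rescaling) are close to but not exactly the
  closed-form targets; validation therefore anchors on the class-hour means,
  which are exact by construction.
* Problem sizes in the test suite (200 recovery replicates, 500 calibration
  replicates, 1000 oracle instances) are the package's own choice, sized to
  bound Monte-Carlo error while keeping the suite within minutes on one CPU.
* Because sex and fat % distributions differ by track in the default cohort,
  the covariate-adjusted group test pays a precision cost (design-driven
  EMM-SE inflation of roughly 1.0–1.3 per track, measured by simulation).
  For the smallest planted effect (time in bed) this puts omnibus replication
  power near 0.89 at the study's sample size; with covariates exogenous to
  track the same effect is detected with power ≈ 0.98. The parameter-recovery
  validation therefore uses permuted (exogenous) covariates, while the
  default pipeline keeps the realistic confounded design.
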