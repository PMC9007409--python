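# Methods

This note documents the models implemented by `reachbias`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical choices that matter when reproducing or
extending the analyses.

## Task variants and geometry

Three task geometries are built in (`experiment_config(1|2|3)`), all with
the start position at the origin, +y along the body midline, angles in
degrees from +y (positive rightward), distances in cm, times in ms from
trial start, and speeds in m/s.

| | targets | onset threshold | exclusions |
|---|---|---|---|
| 1 (blocked frequency) | ±22.5° at 20 cm | 0.05 m/s | >45° or >1000 ms |
| 2 (per-trial probability) | ±22.5° at 20 cm | 0.05 m/s | >45° or >650 ms |
| 3 (explicit choice) | near ±45° at 10 cm, far ±22.5° at 15 cm, rectangle spanning 46° at 7.07 cm depth | 0.02 m/s | >75° or >2500 ms |

Targets are 2 cm discs scored against a 1 cm cursor, so the effective
capture radius is 1.5 cm throughout. The reveal of the correct target is
triggered by movement initiation: 4 cm displacement or 0.1 m/s hand speed
(variants 1–2); in variant 3 the reveal happens when the path intercepts
the rectangle.

## Kinematics

Velocity is estimated by central finite differences with a 2-sample
half-window and no smoothing (a configurable window exists; filtering was
deliberately left out because the synthetic trajectories are noise-free in
position and recorded data should be filtered upstream). Movement onset is
the first sample whose tangential speed exceeds the variant's threshold;
onsets crossing within 20 ms of a local speed minimum are logged as
borderline, standing in for manual verification of onsets. The initial
reach direction is the direction of the velocity vector 100 ms after
onset. End of motion is the first time after the speed peak that speed
stays below the onset threshold for ≥50 ms, else the last sample.
"Completion" for the duration exclusions is the first crossing of the
target distance (shoot-through scoring), clocked from trial start.

## Strategy classification

At every sample from onset to end of motion, each target subtends an
angular window of half-width `asin(capture_radius / distance)` from the
current hand position. T_commit is the first sample whose instantaneous
heading lies inside either window; samples exactly at a target centre are
skipped. A reach is **direct** iff T_commit is strictly earlier than
T_reveal + 60 ms (perceptual delay); equality and never-committing reaches
are **intermediate** (a strict reading of "before"). Variant 3 is
classified geometrically instead — rectangle interception before any near
target ⇒ intermediate — and on simulated sessions the two classifiers
agree on ≥95% of trials at low motor noise.

Outcomes: a reach whose minimum post-onset distance to the incorrect
target is smaller than to the correct target is a **choice error**;
otherwise it is a **hit** if it passes within 1.5 cm of the correct centre
and a **motor error** if not. The path minimum is used rather than the
terminal sample (shoot-through task); the terminal-sample reading is
available behind a flag.

## Bias estimation

All angles are first aligned so the more-rewarded side is positive; in
pure-likelihood blocks (reward 1:1) the frequent side is negative, and in
fully symmetric blocks the block's counterbalance label orients the sign.

Per condition, direct-reach directions are fit with a two-component
Gaussian mixture by EM: means initialised at the two aligned target
directions, sds at 10°, equal proportions; 20 restarts (19 with 3° mean
jitter), tolerance 1e-6 on the log-likelihood, at most 200 iterations, sd
floor 0.01°. The EM is vectorized across restarts, which is what makes
1000 bootstrap iterations × 16 conditions affordable; tests verify it
attains the likelihood of a dense grid search. `D_choice` is the mixing
proportion of the component whose mean is positive — a bounded proportion
directly comparable with the explicit-choice task's count proportion; the
raw positive/negative proportion ratio is also emitted. Fits are invalid
when the component means are closer than 5° or a proportion falls below
0.02. Intermediate directions get a single-Gaussian ML fit; `I_bias` is
its mean. Both fits require 10 trials (the study screened participants at
5% of a block; the per-fit minimum is this package's choice).

Uncertainty comes from a participant-level bootstrap: each of 1000
iterations pools the aligned angles of ⌈0.75 P⌉ participants — sampled
without replacement, the literal reading of "subset"; with-replacement is
a flag — and refits every condition. Iterations with any failed or
invalid fit are dropped and counted. The explicit-choice variant skips
mixture fitting entirely: per participant, `D_choice` is the count
proportion of direct reaches to the positive side and `I_bias` the mean
intermediate direction.

## Weight estimation

For one bootstrap iteration (or participant), ordinary least squares gives
the reward line R(r) through the conditions with likelihood 1:1 and the
likelihood line L(f) through the conditions with reward 1:1 (the 1:1/1:1
condition contributes to both). The predictor is the raw ratio — matching
the scale on which the axis effects are reported — with a log-ratio
option; the per-trial probability variant uses the probability ratio
p/(1−p) (70:30 → 2.33, 80:20 → 4). The frequency weight is the w in

    prediction(f, r) = w · L(f) + (1 − w) · R(r)

minimising the unweighted sum of squared errors over the mixed conditions
(both ratios ≠ 1), found by grid search on [0, 1] in steps of 0.001 with
ties resolved to the smaller w. The closed-form least-squares solution of
the same objective exists (the model is linear in w) and is kept as an
internal cross-check; the grid is the primary path because it makes the
bounded domain and tie-breaking explicit. Distributions of w are compared
against 0.5 with one-sample t tests, against each other with a paired t
and a two-sample Kolmogorov–Smirnov test; zero-variance degenerate inputs
are flagged instead of returning infinities.

## Subjective value

The subjective value of option i is `SV_i = P_i · R_i^α`, and the observed
bias is taken proportional to SV_1/SV_2 = (P1/P2)·(R1/R2)^α. Over the
mixed conditions, bias/(P1/P2) is regressed on the reward ratio in log–log
space, which is exact on noiseless power-law data and avoids nonlinear
optimisation at this scale (a nonlinear refinement can be added behind the
same interface). Intermediate biases are first mapped onto the direct
proportion scale: angle/separation + 0.5, with separation 45°. Direct
biases enter as the raw proportion (not odds); this choice is recorded in
the output metadata (`bias_scale: proportion`). Points with nonpositive
transformed bias are dropped with a log message. On data generated under
the weighted-sum model, the fitted α decreases monotonically with the
generating frequency weight for both measures — more reward weight means
less reward discounting — which is the ordering the weight analysis
implies.

## Risk attitude

The linear point of equivalence regresses P(choose sure bet) on the
sure-bet value (trialwise OLS on the 0/1 outcomes; a binned option
averages per offer first) and reports the value where the line crosses
0.5, clamped to 5–20 cents with a flag — this is the quantity used to set
each participant's base reward. The psychometric indifference point fits a
logistic of gamble choice against EV(gamble) − sure bet and reports the
difference where P(gamble) = 0.5; complete separation falls back to a
ridge-penalized likelihood (penalty 1e-3) and is flagged. The lapse rate
is fixed at 0. Cohort outliers are flagged at |z| > 3 (configurable);
correlation analyses report results both with and without them.

## Generative choice model and parameter recovery

The recovery harness implements the generative simulation that validates
the weight estimator. For a condition with frequency ratio f (favouring
target 2) and reward ratio r (favouring target 1):

    pref_f = (1/(1+f) − 0.5) · w_f + 0.5
    pref_r = (r/(1+r) − 0.5) · w_r + 0.5,  with w_r = 1 − w_f
    P(T1)  = pref_f·pref_r / (pref_f·pref_r + (1−pref_f)(1−pref_r))

Direct reaches Bernoulli-sample P(T1) (200 trials/condition); intermediate
directions are the deterministic mapping 30°·P − 15° (an optional angular
noise term defaults to 0). All nine frequency × reward combinations of the
explicit-choice design {1, 2, 4}² are simulated; the near/far manipulation
does not enter these formulas and is ignored. Estimation then runs the
weights module exactly as on real data, with count-proportion `D_choice`.

Two properties of this harness matter for interpreting recovery numbers.
First, the estimator interpolates *linear* axis fits while the generative
choice rule is nonlinear in the ratios, so even in the noiseless limit the
recovered weight carries an intrinsic method bias, largest (±0.048) at
simulated weights 0.2 and 0.8 on the {1, 2, 4} grid. Second, the direct
measure adds binomial noise (per-iteration SD ≈ 0.10 at 200
trials/condition), so the median over 25 iterations moves by ±0.025 around
that bias and the worst grid point typically lands near 0.08 from the
truth. Medians are monotone in the simulated weight and direct vs
intermediate recoveries are strongly correlated; a ±0.05 accuracy claim at
every grid point, however, holds only for the noiseless intermediate
measure.

## Synthetic sessions

The simulator exists to give every downstream stage inputs with known
ground truth; it emulates the study conditions, not arm biomechanics.

- **Design.** Variant 1: 16 blocks (frequency × reward ∈ {1, 2, 5, 10}²,
  opposed — the more-rewarded side is the less-frequent side — rewarded
  side alternating across blocks), 36 trials/block by default. Variant 2:
  reward blocks {1, 2, 5} with per-trial probability ratios {1, 7/3, 4}
  balanced within block. Variant 3: {1, 2, 4}² × near/far reward ratios
  {1, 2.5, 4}. The correct side is drawn per trial with
  P(frequent) = f/(1+f).
- **Choices.** Per trial a strategy is drawn Bernoulli(p_intermediate)
  (no strategy dynamics). Condition biases follow the weighted-sum model
  the estimation assumes: pure-axis conditions lie on linear per-unit-ratio
  effect lines, mixed conditions are their w_f-weighted combination. The
  default axis slopes are the group-level effects reported for the blocked
  task (+0.01/−0.04 per unit ratio on the direct choice proportion,
  +0.12/−0.37 °/ratio for the intermediate direction). Generating under
  the estimator's own model makes the full stack exactly identifiable in
  the large-sample limit, which is what end-to-end recovery tests require;
  the nonlinear EV-normalisation rule above is deliberately reserved for
  the recovery harness, whose point is to probe the estimator under that
  model. Direct reaches aim at the chosen target plus Gaussian angular
  noise (motor_sd, default 2°); intermediate reaches launch at the
  condition bias plus the same noise.
- **Kinematics.** 100 Hz sampling by default (configurable to 1000 Hz;
  all thresholds are rate-independent — 100 Hz keeps the test suite an
  order of magnitude faster at no cost to any estimate). A 200 ms
  stationary hold precedes movement. Speed follows a minimum-jerk bell
  over a nominal distance 1.3× the target distance (slack for curvature),
  with movement times 600/450/600 ms for variants 1/2/3-direct and
  1200 ms for the far reach — peak speeds ≥ 0.3 m/s, completions inside
  every exclusion limit — plus a small floor late in the movement so the
  shoot-through distance is always crossed. Intermediate reaches steer
  toward the revealed target at 0.8 °/ms starting reaction_ms (default
  150 ms) after the reveal; the rate is chosen so the far target remains
  reachable after the rectangle reveal in variant 3.
- **Utility assay.** P(gamble) = logistic(slope · (EV difference −
  indifference point)), sure bets 2–18¢ against a 0/20¢ gamble.
- **Individual differences.** The profile's `near_far_slope` (default 0)
  shifts p_intermediate with the near/far reward ratio so the
  explicit-choice sensitivity analyses have structure to recover.

What the generator does **not** emulate — and hence what passing tests do
not demonstrate about recorded data: measurement noise and filtering
artifacts in position traces; online corrections within direct reaches
(they are straight, so a noisy direct reach that misses both target
windows never commits and is labelled intermediate, a ~3% contamination at
the default motor noise that real corrective behaviour would reduce);
reaction-time variability (fixed latency); learning or sequential effects
across trials; and any relationship between biases and the correct-side
sequence. Recovered-weight accuracy on synthetic cohorts is limited by
per-condition binomial noise in the direct measure: at the blocked task's
own scale (24 participants × 36 trials/block) single-cohort estimates
scatter ±0.03–0.05 around the generating weights, so cohort-level claims
are evaluated as medians over a few simulation seeds.

## Numerical choices and degenerate inputs

- Angles are wrapped to (−180°, 180°], boundary ties toward positive.
- EM: restarts/jitter/tolerance as above; mixture validity thresholds 5°
  separation and 0.02 minimum proportion.
- Weight grid step 0.001; ties to the smaller w; closed-form cross-check.
- OLS lines require ≥2 distinct ratios per axis; weight search requires
  ≥1 mixed condition; α fits require ≥2 distinct reward ratios after
  dropping nonpositive points.
- Error-effect models drop zero-variance predictors (e.g. a cohort with
  no motor errors) with a record, and name collinear terms when the
  design matrix is rank-deficient. No multiple-testing correction is
  applied anywhere (raw p-values are reported, noted in the report
  metadata).
- Bootstrap iterations and recovery iterations are flagged/dropped with
  counts, never silently; reports carry full exclusion accounting
  (trials in = kept + dropped per reason) and seed provenance.

## Known limitations

- The two-target analysis pools participants (population-level bootstrap);
  hierarchical pooling is out of scope.
- Weight estimates from the per-trial probability variant are
  ill-conditioned at realistic sample sizes: its axis effects (≈0.009 and
  −0.11 per unit ratio on the proportion scale) are comparable to the
  per-condition sampling noise, so per-cohort weights have very large
  spread. This mirrors the large spreads the probability variant is known
  for and is not specific to this implementation.
- The importer for externally deposited raw data is a stub
  (`read_osf_deposit`); no standard layout exists for such deposits, and
  all shipped analyses run on synthetic or CSV data.
- Soft/probabilistic strategy classification and change-of-mind detection
  within intermediate reaches are non-goals.
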