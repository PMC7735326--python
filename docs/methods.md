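# Methods

`shuttlesim` models a *dynamic shuttlebox*: a two-chamber arena whose water
temperatures ramp according to which side a fish occupies, so that holding a
preferred body temperature requires active shuttling.  The package has three
layers — a closed-loop simulator with thermoregulating agents, the
behavioural metrics derived from 1 Hz tracks, and the statistical analyses —
plus a pipeline that ties them together.  This note records the model, its
assumptions, the defaults and why, the numerical choices, and what the
simulation does and does not establish about real data.

## The closed loop

Both chambers hold a fixed offset (default 3 °C, right warmer).  While the
fish occupies the left (cold) side both chambers cool at `ramp_rate`
(default 0.5 °C min⁻¹); on the right side both warm, within hard limits
(default 15–35 °C).  Cooling clamps when the left chamber reaches the lower
limit and warming when the right chamber reaches the upper limit, so the
offset invariant is preserved exactly at the clamp (to one double-precision
ulp in floating point — the pair is advanced by updating the driven chamber
and adding/subtracting the offset, never by integrating both independently).
The controller is inactive during habituation (first hour; left chamber at
`housing_temp − 1.5` = 25.5 °C) and active through the ramping, gas and test
phases.  Phase boundaries fall on exact minute marks; the time base is
seconds at 1 Hz.

## Body temperature

Small fish equilibrate quickly with the surrounding water, so body
temperature is reconstructed with a one-step lag average of the occupied
chamber's temperature:

    T_B(0) = T_occupied(0),
    T_B(t) = (T_occupied(t) + T_B(t−1)) / 2.

At constant chamber temperature the gap |T_B − T| halves each sample
(exactly geometric, factor ½), which the tests assert bit-tightly.  The
recurrence is evaluated as a first-order IIR filter (`scipy.signal.lfilter`)
with the initial condition arranged so the first sample equals the occupied
chamber's temperature; an explicit-loop oracle in the tests checks the
arithmetic.  Occupancy comes from the sign of x (midline at x = 0, +x to the
right); a sample at exactly x = 0 keeps the previous side, which avoids
double-counting crossings.

## The fish agent

Tracking data record *behaviour*, not a behavioural rule, so the agent's
decision model is configuration, not biology:

- **Dual escape thresholds.** When T_B rises to `set_point + δ_U` the agent
  heads for the cold side; when it falls to `set_point − δ_L`, for the warm
  side.  Defaults δ_U = δ_L = 1.5 °C: together with the 3 °C offset this
  produces an oscillation band of ≈3 °C whose midpoint is the set point, so
  the time-averaged T_B estimates the set point and the lower/upper escape
  temperatures sit at `set_point ∓ 1.5` °C (verified to within 0.5 °C as a
  median over seeds).
- **Movement.** Per-second displacement magnitudes are log-normal (default
  median 2 cm s⁻¹, log-sd 0.5).  Between thresholds the agent performs a
  bounded random walk within its chamber, reflected off the walls and a
  0.5 cm midline margin, so midline crossings happen only through deliberate
  shuttles.  The arena is 15 cm per side; depth y is normalized to [0, 1]
  (surface at 1, "at surface" above 0.9) and converted with a 20 cm water
  column for velocity.
- **Quiescence.** An absorbing per-second hazard models fish that stop
  shuttling altogether and remain confined to one side (defaults: 0 for
  controls, 10⁻⁵ s⁻¹ for treated fish — over a 4.5 h exposure roughly one in
  seven treated fish quiesces).  A quiescent fish on the cold side drifts to
  the lower clamp, slightly steepening the measured group difference, as in
  the motivating observations.
- **Surfacing.** Depth is drawn each second from a Bernoulli surfacing model
  with logit-linear terms: baseline (2 % surfacing odds), an H₂S term
  (ln 17) and a warm-water term (ln 3.5) that switches on when T_B exceeds
  24.5 °C, the midpoint of the surfacing assay's two temperatures.

Treatment effects — the set-point shift (default 6 °C), the log-speed shift
(+0.15), the quiescence hazard and the surfacing H₂S odds — switch on at gas
onset.  Applying them from trial start would contaminate the treated group's
ramping-phase means, which the set-point regression uses as the
within-individual baseline.

## Cohorts

Fish i's baseline set point is Normal(`mean_set_point`, σ_b²) with
σ_b = 1.5 °C; each phase adds independent Normal(0, σ_w²) wobble.  The
default σ_w = 1.4 °C was chosen so the control group's ramping-vs-test ICC
of phase means sits near 0.53 = 2.25/(2.25 + 1.96), the moderate
repeatability regime the analyses are designed for; recovery studies that
require persistent set points set σ_w = 0 explicitly.  Randomness is
organized as one `SeedSequence` per cohort spawning per-fish child streams,
so every generator is a pure function of (inputs, seed).

## Metrics

Per fish and phase: mean T_B; side preference `2·(0.5 − Time_{x<0}/Time)`
(−1 = always left/cold — the formula is implemented verbatim, so *negative*
values mean cold-side preference); shuttle rate (midline sign changes per
minute; an optional dead-band makes crossings count only after |x| exceeds
the band on the new side, for noisy real tracks — default 0); LET/UET as the
per-phase mean of the last T_B before each crossing out of the cold/warm
side, left undefined (NaN) when a direction has no events; mean log swim
speed from (x, y·depth) displacements with speeds floored at 0.01 cm s⁻¹
before the log; and the fraction of samples above the surface threshold.
Samples after a recorded termination time are excluded and the termination
is flagged on every summary row; partial phases contribute their partial
data.

## Statistical stages

- **Treatment comparisons** are OLS fits of `metric ~ treatment`
  (equivalently pooled-variance t-tests) with t-based 95 % CIs, two-tailed
  at α = 0.05; Welch's unequal-variance test is available for one-tailed
  pilot-style contrasts, and rates/velocities can be log-transformed first.
  No multiplicity adjustment is applied (per-metric inference).
- **Set-point regression.**  `test ~ ramping × treatment`.  A pure set-point
  shift predicts a common slope near unity with an intercept offset and no
  interaction; an escape-to-the-coldest-corner response would produce an
  interaction.  The interaction is tested in the full model, but the slope
  and intercept shift are reported from the additive model: on the raw
  scale the full model's "shift" coefficient is the extrapolated group
  difference at a ramping mean of 0 °C, which is meaningless here.  The
  additive estimate equals the constructed shift exactly on noiseless data.
  Single-group inputs fit the plain line (slope only).
- **Repeatability** is the one-way random-effects ICC,
  `R = (MSB − MSW)/(MSB + (k−1)·MSW)`, truncated at zero (the raw value is
  retained).  The 95 % CI is a parametric bootstrap (default 1000 draws)
  from the fitted variance components; the p-value permutes measurements
  across individuals (default 1000; `(1 + #{R* ≥ R}) / (n+1)`, computed on
  the untruncated statistic to avoid ties at the boundary).
- **Difference smoothing.**  Each fish's binned T_B series (default 1-min
  bins) is prewhitened with the exact AR(1) transform at fixed ρ = 0.95
  (first observation scaled by √(1−ρ²)); a reference curve plus a
  treated-difference curve, both cubic B-splines (default 20 basis
  functions, uniform interior knots) with second-difference penalties, are
  fitted by penalized least squares with one GCV-chosen penalty.  Pointwise
  95 % bands come from the sandwich covariance of the penalized estimator.
  This deliberately simplifies a full GAM with per-individual random
  smooths to population curves over fish-level series; the null-coverage
  and constructed-offset tests bound what that simplification costs.
- **Shuttle counts** per 1-min bin are modelled as zero-inflated Poisson:
  `P(0) = π + (1−π)e^{−λ}`, positive counts Poisson scaled by (1−π).  The
  MLE is computed by EM over latent structural-zero indicators (monotone in
  the log-likelihood; matched against a 200×200 grid-search oracle and
  against an independent ML implementation in the tests), with Wald
  intervals from the numerical observed information on the (logit π, log λ)
  scale.  Boundary cases (all zeros; π → 0) are flagged, with the plain
  Poisson information used for λ when π is at zero.  Group comparisons use
  a likelihood-ratio test of shared versus per-group (π, λ), χ² with 2
  degrees of freedom per extra group.  The 1-min bin matches the rate's
  min⁻¹ unit.
- **Surfacing odds.**  Surfacing-frame counts are a binomial GLM on
  indicators for H₂S, warm water and their interaction (treatment coding;
  reference 0 % H₂S at the cool temperature), fitted by maximum likelihood
  with Wald 95 % intervals; odds ratios are exponentiated coefficients.
  This replaces an MCMC binomial model with the same estimand — at these
  sample sizes (thousands of frames per fish) Wald intervals and posterior
  credible intervals are close.  A design cell with surfacing fraction 0
  or 1 (separation) triggers a warning and a lightly ridge-penalized
  Newton fit (λ = 10⁻⁴) instead of unbounded estimates.

## Recovery studies and problem sizes

`shuttlesim.recovery` packages the validation studies the acceptance script
reruns: 20 replicate cohorts of 20 control + 17 treated fish simulated
through the full 7.5 h protocol at 1 Hz (treatment effect on test-phase
mean T_B, and the control-arm regression slope); 20 replicates of 20 fish ×
2 phase means at true ICC 0.54; and 20 replicates of the 2×2 surfacing
factorial (6 fish per cell × 3600 frames, true odds ratios 17 and 3.5).
Medians over replicates are reported.  These sizes mirror the study design
they emulate and keep a full rerun under a minute on one core.

## What the simulation does not show

The generator produces idealized data: no tracking noise or dropout, no
learning during ramping (set points are constant within a phase), no
within-trial drift of preference other than the phase wobble, hard-switch
treatment onset, and a memoryless quiescence process.  Passing recovery
tests therefore demonstrates that the *pipeline* is consistent — it
recovers the truths the generator encodes, at realistic sample sizes and
effect magnitudes — not that the agent model is a faithful account of fish
behaviour.  Analyses of real tracks should revisit the dead-band width for
midline jitter, the velocity floor, and the fixed ρ.

## Degenerate inputs and tie-breaks

x = 0 keeps the previous side everywhere (occupancy, crossing detection).
Escape temperatures with no events in a direction are NaN and excluded from
group comparisons; a comparison group with fewer than two defined values
aborts with the group named, except in the pipeline's comparison sweep where
the metric is flagged and skipped.  Constant input to the smoother returns
flat curves; ρ = 0 reduces the prewhitening to the identity.  All-zero
count vectors report π = 1 with λ flagged unidentifiable.  Log transforms
reject non-positive values rather than flooring them silently (the pipeline
falls back to the identity scale with a logged warning when a quiescent
fish has a zero rate).
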