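# shuttlesim

Virtual dynamic-shuttlebox experiments for behavioural thermoregulation
studies in fish, with the full analysis pipeline used to ask whether a
treatment (e.g. dissolved hydrogen sulfide) lowers the defended thermal set
point.

In a dynamic shuttlebox, two chambers hold a fixed temperature offset
(right warmer by 3 °C) and both ramp down while the fish occupies the cold
side and up while it occupies the warm side (±0.5 °C min⁻¹ within
15–35 °C).  A fish that defends a preferred body temperature must shuttle
across the midline, and the oscillation band of its reconstructed body
temperature

    T_B(t) = (T_occupied(t) + T_B(t−1)) / 2

straddles the set point it defends.  `shuttlesim` provides:

- **`shuttlesim.sim`** — the closed-loop controller, thermoregulating fish
  agents (dual escape thresholds δ_U/δ_L around an individual set point,
  log-normal step lengths, an absorbing "stopped shuttling" hazard, a
  Bernoulli surfacing model), cohort generation with between-fish
  (σ_b = 1.5 °C) and phase-to-phase (σ_w) set-point variation and a
  treatment shift Δ applied from gas onset, and the 2×2
  H₂S × temperature surfacing assay generator.
- **`shuttlesim.metrics`** — body temperature with thermal lag, shuttle
  detection (optional hysteresis), side preference
  `2·(0.5 − Time_{x<0}/Time)`, lower/upper escape temperatures (LET/UET),
  log swim velocity and surface-respiration fraction, per fish and phase.
- **`shuttlesim.inference`** — treatment comparisons (OLS / Welch, log
  transforms), the ramping-vs-test set-point regression (slope ≈ 1 plus an
  intercept shift, *without* interaction, is the signature of a true
  set-point change), ANOVA repeatability R with parametric-bootstrap CIs
  and permutation p-values, penalized-B-spline difference smoothing of
  AR(1)-prewhitened T_B time courses (ρ = 0.95), zero-inflated Poisson
  shuttle-count models fitted by EM, and the binomial GLM of surfacing
  odds.
- **`shuttlesim.recovery`** — parameter-recovery studies that validate the
  whole chain against known generative truths.

See `docs/methods.md` for the model, defaults and numerical choices.

## Worked example

Run the full pipeline (simulate a 20 control + 17 treated cohort through the
7.5 h protocol at 1 Hz, derive metrics, run all analyses):

```sh
shuttlesim run --seed 42 --out demo/
```

`demo/report.txt` then contains (abridged):

```
== Treatment comparisons (test phase) ==
mean_T_B (identity): effect -6.706 CI [-8.300, -5.111] p=4.453e-10 (n=20+17)
LET (identity): effect -6.345 CI [-7.769, -4.921] p=1.389e-10 (n=19+17)
UET (identity): effect -6.348 CI [-7.771, -4.924] p=1.366e-10 (n=19+17)

== Ramping vs test set-point regression ==
slope 0.672 CI [0.410, 0.934] p=9.271e-06
treatment intercept shift -6.030 CI [-7.266, -4.794] p=1.461e-11
interaction -0.388 CI [-0.917, 0.141] p=0.1454
set-point-shift verdict: True

== Repeatability (control, ramping vs test mean T_B) ==
R = 0.838 CI [0.635, 0.934] p=0.000999 (n=20 fish)

== Aquatic surface respiration binomial GLM ==
h2s: 2.791 log-odds CI [2.693, 2.889] OR 16.30 p=0
temp: 1.227 log-odds CI [1.120, 1.334] OR 3.41 p=1.565e-111
h2s:temp: 0.007 log-odds CI [-0.107, 0.122] OR 1.01 p=0.8987
```

Reading it: treated fish hold a body temperature ≈6.7 °C below controls,
with both escape temperatures shifted by the same amount — the whole
defended band moved.  The regression shows an intercept shift of −6.0 °C
with no slope interaction (the generative truth is a −6 °C set-point
shift), so the verdict is a set-point change rather than an escape
response.  Control fish are individually repeatable across phases
(R = 0.84 here), and surfacing odds rise ≈16-fold under H₂S and ≈3.4-fold
in warm water, close to the generator's 17× and 3.5×.

Stage-level commands (`shuttlesim simulate / metrics / analyze / asr-sim /
asr-fit`) operate on CSV artifacts; `examples/config.yaml` documents every
configurable knob.  The library surface mirrors the CLI, e.g.:

```python
from shuttlesim import (TrialConfig, FishAgentParams, simulate_trial,
                        summarize)
track = simulate_trial(TrialConfig(), FishAgentParams(set_point=27.3), seed=1)
for s in summarize(track):
    print(s.phase, round(s.mean_T_B, 2), round(s.shuttle_rate, 2))
```

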