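"""Parameter-recovery studies: can the pipeline recover known truths?

Each study simulates data with known generative parameters at the study's
sample sizes (20 control / 17 treated fish; 20 fish with two phase means;
six fish per surfacing-assay cell), runs the full analysis pipeline, and
reports per-replicate estimates.  Medians over replicates summarize what the
estimator recovers under the study conditions.
"""

from __future__ import annotations

import numpy as np

from .inference import asr_glm, compare_treatments, ramping_test_model, repeatability
from .metrics import summaries_to_frame, summarize
from .params import PopulationParams, TrialConfig
from .sim import (
    DEFAULT_ASR_COEFFICIENTS,
    DEFAULT_ASR_DESIGN,
    generate_asr,
    generate_cohort,
)

__all__ = [
    "setpoint_shift_study",
    "icc_recovery_study",
    "asr_recovery_study",
]


def _rep_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def setpoint_shift_study(
    n_reps: int = 20,
    seed: int = 0,
    pop: PopulationParams | None = None,
    cfg: TrialConfig | None = None,
) -> dict:
    """Simulate full trials and recover the treatment set-point shift.

    Default population: control set points Normal(27.3, 1.5²) °C, a 6 °C
    anapyrexic shift for the 17 treated fish, no phase-to-phase wobble.  Each
    replicate runs simulate -> summarize -> treatment comparison of test-phase
    mean T_B, plus the ramping-vs-test regression on the control arm (the
    control fish are exactly a 20-fish control cohort with persistent
    individual set points).

    Returns per-replicate ``delta_estimates`` (absolute treatment effect, °C)
    and control-arm ``slopes``.
    """
    if pop is None:
        pop = PopulationParams(
            mean_set_point=27.3,
            between_fish_sd=1.5,
            within_fish_sd=0.0,
            treatment_shift=6.0,
            n_control=20,
            n_treated=17,
        )
    if cfg is None:
        cfg = TrialConfig()
    deltas = []
    slopes = []
    for s in _rep_seeds(seed, n_reps):
        tracks, _ = generate_cohort(pop, cfg, int(s))
        summaries = []
        for t in tracks:
            summaries.extend(summarize(t))
        sdf = summaries_to_frame(summaries)
        res = compare_treatments(sdf, "mean_T_B", "test")
        deltas.append(abs(res.estimate))
        ctl = sdf[sdf["treatment"] == res.reference]
        reg = ramping_test_model(ctl)
        slopes.append(reg.slope)
    return {
        "delta_estimates": np.asarray(deltas),
        "slopes": np.asarray(slopes),
        "n_control": pop.n_control,
        "n_treated": pop.n_treated,
    }


def icc_recovery_study(
    n_reps: int = 20,
    seed: int = 0,
    n_fish: int = 20,
    var_between: float = 1.174,
    var_within: float = 1.0,
    k: int = 2,
) -> dict:
    """Recover the intraclass correlation from synthetic phase means.

    Fish baselines have variance ``var_between``; each of ``k`` phase
    measurements adds independent noise of variance ``var_within``, so the
    true ICC is ``var_between / (var_between + var_within)`` (0.54 at the
    defaults).  Returns per-replicate point estimates ``R``.
    """
    estimates = []
    for s in _rep_seeds(seed, n_reps):
        rng = np.random.default_rng(int(s))
        base = rng.normal(0.0, np.sqrt(var_between), n_fish)
        a = base[:, None] + rng.normal(0.0, np.sqrt(var_within), (n_fish, k))
        r = repeatability(a, n_boot=0, n_perm=0)
        estimates.append(r.R)
    return {
        "R_estimates": np.asarray(estimates),
        "true_icc": var_between / (var_between + var_within),
        "n_fish": n_fish,
    }


def asr_recovery_study(
    n_reps: int = 20,
    seed: int = 0,
    design=DEFAULT_ASR_DESIGN,
    coefficients=DEFAULT_ASR_COEFFICIENTS,
) -> dict:
    """Recover surfacing log-odds coefficients from the 2x2 factorial.

    Generates the default assay (six fish per {H2S} x {temperature} cell,
    3600 frames each; true odds ratios 17 for H2S and 3.5 for warm water, no
    interaction) and fits the logistic model with its interaction term.
    Returns per-replicate H2S and temperature log-odds coefficients.
    """
    h2s = []
    temp = []
    for s in _rep_seeds(seed, n_reps):
        trials = generate_asr(design, coefficients, int(s))
        fit = asr_glm(trials)
        h2s.append(fit.coefficient("h2s"))
        temp.append(fit.coefficient("temp"))
    n_fish = sum(row[2] for row in design)
    return {
        "h2s_coefs": np.asarray(h2s),
        "temp_coefs": np.asarray(temp),
        "n_fish": n_fish,
    }
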