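"""Virtual dynamic shuttlebox: controller, fish agents, cohorts, ASR assay.

The closed loop works like the physical apparatus: both chambers hold a fixed
temperature offset (right warmer); while the fish occupies the left side both
chambers cool at ``ramp_rate`` °C/min, while it occupies the right side both
warm, within hard limits.  A thermoregulating agent therefore has to shuttle
to keep its body temperature near its set point, and the resulting
oscillation band straddles that set point.

The fish decision rule is deliberately simple and documented as configuration,
not biology: body temperature follows the one-step lag recurrence
``T_B(t) = (T_chamber(t) + T_B(t-1)) / 2``; when it exceeds
``set_point + delta_upper`` the agent heads for the cold side, below
``set_point - delta_lower`` for the warm side, and otherwise performs a
bounded random walk within its current chamber with log-normal per-second
step lengths.  A small absorbing per-second hazard models fish that stop
shuttling altogether after gas exposure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import (
    PHASES,
    ASRTrial,
    ChamberState,
    FishAgentParams,
    PopulationParams,
    TrialConfig,
)

__all__ = [
    "AgentState",
    "step_controller",
    "step_fish",
    "simulate_trial",
    "generate_cohort",
    "generate_asr",
    "DEFAULT_ASR_DESIGN",
    "DEFAULT_ASR_COEFFICIENTS",
]

#: Body temperature dividing the "cool" from the "warm" surfacing regime;
#: midpoint of the two assay temperatures (21 and 28 °C).
SURFACE_TEMP_SPLIT = 24.5

#: Minimum distance (cm) the random walk keeps from the midline so that
#: midline crossings happen only through deliberate shuttles.
WANDER_MARGIN_CM = 0.5

_SIDE_CODE = {"left": -1, "right": 1, -1: -1, 1: 1}


def _advance_temps(
    T_left: float,
    T_right: float,
    side: int,
    active: bool,
    step_deg: float,
    lo: float,
    hi: float,
    offset: float,
) -> tuple[float, float]:
    """One controller step on the chamber temperature pair.

    Cooling clamps when the left chamber reaches the lower limit, warming when
    the right chamber reaches the upper limit, so the offset is preserved
    exactly at all times.
    """
    if not active:
        return T_left, T_right
    if side < 0:  # fish on the cold side -> cool both chambers
        T_left = max(T_left - step_deg, lo)
        T_right = T_left + offset
    else:  # fish on the warm side -> warm both chambers
        T_right = min(T_right + step_deg, hi)
        T_left = T_right - offset
    return T_left, T_right


def step_controller(
    state: ChamberState, fish_side, dt: float, cfg: TrialConfig
) -> ChamberState:
    """Advance the closed-loop temperature controller by ``dt`` seconds.

    ``fish_side`` is ``"left"``/``"right"`` (or -1/+1).  During habituation
    (``controller_active`` False) temperatures are unchanged.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    try:
        side = _SIDE_CODE[fish_side]
    except (KeyError, TypeError):
        raise ValueError(f"invalid fish side: {fish_side!r}") from None
    lo, hi = cfg.temp_limits
    step_deg = cfg.ramp_rate * dt / 60.0
    T_left, T_right = _advance_temps(
        state.T_left,
        state.T_right,
        side,
        state.controller_active,
        step_deg,
        lo,
        hi,
        cfg.chamber_offset,
    )
    return ChamberState(
        t=state.t + dt,
        T_left=T_left,
        T_right=T_right,
        controller_active=state.controller_active,
    )


@dataclass(slots=True)
class AgentState:
    """Mutable state of one simulated fish.

    ``side`` is -1 (left/cold) or +1 (right/warm); ``target`` is the side the
    agent is currently heading for (0 when inside its thermal dead band).
    """

    x: float
    y: float
    T_B: float
    side: int
    target: int = 0
    quiescent: bool = False
    quiescent_since: float | None = None


def step_fish(
    state: AgentState,
    chambers: ChamberState,
    dt: float,
    params: FishAgentParams,
    rng: np.random.Generator | None = None,
    *,
    h2s_on: bool = False,
    half_width: float = 15.0,
    surface_threshold: float = 0.9,
    draws: tuple[float, int, float, float, float] | None = None,
) -> AgentState:
    """Advance one fish agent by ``dt`` seconds (mutates and returns state).

    The agent first (possibly) enters the absorbing quiescent mode, then picks
    a target side by comparing its current body temperature against the dual
    escape thresholds, moves (directed toward the target side, or a bounded
    random walk within its chamber), and finally updates body temperature from
    the chamber it now occupies and draws its depth from the per-frame
    surfacing Bernoulli model.

    ``draws`` optionally supplies the step's random numbers
    ``(speed_cm_s, wander_sign, u_quiesce, u_surface, v_depth)`` so callers
    can pre-draw vectorized streams; otherwise they come from ``rng``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not math.isfinite(state.T_B):
        raise ValueError("agent body temperature must be finite")
    if draws is None:
        if rng is None:
            raise ValueError("either rng or draws must be provided")
        speed = float(
            rng.lognormal(params.speed_log_mean, params.speed_log_sd)
        )
        wander_sign = 1 if rng.random() < 0.5 else -1
        u_q = float(rng.random())
        u_s = float(rng.random())
        v_y = float(rng.random())
    else:
        speed, wander_sign, u_q, u_s, v_y = draws

    # Absorbing quiescence: the fish permanently stops shuttling and stays
    # confined to its current side.
    if not state.quiescent and params.quiescence_hazard > 0.0:
        if u_q < params.quiescence_hazard * dt:
            state.quiescent = True
            state.quiescent_since = chambers.t

    # Target selection from the current body temperature (dual thresholds).
    if state.quiescent:
        state.target = 0
    elif state.T_B >= params.set_point + params.delta_upper:
        state.target = -1  # too warm -> seek the cold (left) side
    elif state.T_B <= params.set_point - params.delta_lower:
        state.target = 1  # too cold -> seek the warm (right) side
    else:
        state.target = 0

    step_len = speed * dt
    if state.target != 0 and state.target != state.side:
        # Directed crossing toward the other chamber.
        x = state.x + state.target * step_len
        if x > half_width:
            x = half_width
        elif x < -half_width:
            x = -half_width
        if x == 0.0:
            x = state.target * 1e-9
        state.x = x
        state.side = -1 if x < 0 else 1
    else:
        # Bounded random walk within the current chamber, reflected off the
        # walls and a small midline margin.
        if state.side < 0:
            lo_b, hi_b = -half_width, -WANDER_MARGIN_CM
        else:
            lo_b, hi_b = WANDER_MARGIN_CM, half_width
        x = state.x + wander_sign * step_len
        if x > hi_b:
            x = 2.0 * hi_b - x
        if x < lo_b:
            x = 2.0 * lo_b - x
        state.x = min(max(x, lo_b), hi_b)

    # Body temperature lag recurrence against the now-occupied chamber
    # (identical arithmetic to behaviour_metrics.body_temperature).
    T_occ = chambers.T_left if state.side < 0 else chambers.T_right
    state.T_B = 0.5 * (T_occ + state.T_B)

    # Per-frame surfacing draw.
    logit = params.surface_logit_base
    if h2s_on:
        logit += params.surface_logit_h2s
    if state.T_B >= SURFACE_TEMP_SPLIT:
        logit += params.surface_logit_temp
    p_surf = 1.0 / (1.0 + math.exp(-logit))
    if u_s < p_surf:
        state.y = surface_threshold + (1.0 - surface_threshold) * v_y
    else:
        state.y = surface_threshold * v_y
    return state


def _phase_params(
    params: FishAgentParams, phase_overrides: dict | None
) -> tuple[list[FishAgentParams], list[bool]]:
    """Materialize per-phase parameter sets and H2S exposure flags."""
    per_phase: list[FishAgentParams] = []
    h2s_flags: list[bool] = []
    for ph in PHASES:
        ov = dict((phase_overrides or {}).get(ph, {}))
        h2s_flags.append(bool(ov.pop("h2s_on", False)))
        unknown = set(ov) - {"set_point", "quiescence_hazard", "speed_log_mean"}
        if unknown:
            raise ValueError(f"unknown phase override keys: {sorted(unknown)}")
        per_phase.append(params.with_(**ov) if ov else params)
    return per_phase, h2s_flags


def simulate_trial(
    cfg: TrialConfig,
    params: FishAgentParams,
    seed,
    *,
    fish_id: str = "fish_0",
    treatment: str = "control",
    phase_overrides: dict | None = None,
    info_out: dict | None = None,
) -> "TrackSeries":
    """Simulate one full shuttlebox trial at the configured sample rate.

    The fish is introduced to the left chamber (set ``initial_left_temp``,
    1.5 °C below housing by default); the controller is inactive during
    habituation and active for the ramping, gas and test phases.

    ``phase_overrides`` maps phase name to overrides of ``set_point``,
    ``quiescence_hazard``, ``speed_log_mean`` and the ``h2s_on`` exposure flag
    — this is how treatment effects switching on at gas onset are expressed.
    ``seed`` may be an int or a :class:`numpy.random.SeedSequence`.  Output is
    a pure function of (cfg, params, overrides, seed).
    """
    from .params import TrackSeries  # local import to avoid cycle confusion

    per_phase, h2s_flags = _phase_params(params, phase_overrides)
    counts = cfg.phase_samples()
    n = sum(counts.values())
    if n < 1:
        raise ValueError("trial has no samples; check phase durations")
    dt = cfg.dt

    phase_idx = np.repeat(np.arange(4), [counts[ph] for ph in PHASES])
    phase_labels = np.array(PHASES, dtype=object)[phase_idx]
    t = np.arange(n, dtype=float) * dt

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    # Pre-drawn streams (one per sample): standard normals for log speed,
    # wander signs, and uniforms for quiescence / surfacing / depth.
    z_speed = rng.standard_normal(n)
    wander = np.where(rng.random(n) < 0.5, 1, -1)
    u_quiesce = rng.random(n)
    u_surface = rng.random(n)
    v_depth = rng.random(n)
    mus = np.array([p.speed_log_mean for p in per_phase])
    speeds = np.exp(mus[phase_idx] + params.speed_log_sd * z_speed)

    lo, hi = cfg.temp_limits
    offset = cfg.chamber_offset
    step_deg = cfg.ramp_rate * dt / 60.0
    W = cfg.half_width_cm
    thr = cfg.surface_threshold

    x_arr = np.empty(n)
    y_arr = np.empty(n)
    Tl_arr = np.empty(n)
    Tr_arr = np.empty(n)

    T_left = cfg.left_start_temp
    T_right = T_left + offset
    state = AgentState(
        x=-W / 2.0, y=0.0, T_B=T_left, side=-1, target=0
    )
    chambers = ChamberState(t=0.0, T_left=T_left, T_right=T_right,
                            controller_active=False)

    # Sample 0: fish at rest in the left chamber; body temperature initialized
    # to the occupied (left) chamber temperature; depth from the surfacing draw.
    p0 = per_phase[phase_idx[0]]
    logit0 = p0.surface_logit_base + (
        p0.surface_logit_h2s if h2s_flags[phase_idx[0]] else 0.0
    ) + (p0.surface_logit_temp if state.T_B >= SURFACE_TEMP_SPLIT else 0.0)
    if u_surface[0] < 1.0 / (1.0 + math.exp(-logit0)):
        state.y = thr + (1.0 - thr) * v_depth[0]
    else:
        state.y = thr * v_depth[0]
    x_arr[0], y_arr[0] = state.x, state.y
    Tl_arr[0], Tr_arr[0] = T_left, T_right

    for i in range(1, n):
        ph = phase_idx[i]
        active = ph >= 1
        T_left, T_right = _advance_temps(
            T_left, T_right, state.side, active, step_deg, lo, hi, offset
        )
        chambers.t = t[i]
        chambers.T_left = T_left
        chambers.T_right = T_right
        chambers.controller_active = active
        step_fish(
            state,
            chambers,
            dt,
            per_phase[ph],
            h2s_on=h2s_flags[ph],
            half_width=W,
            surface_threshold=thr,
            draws=(speeds[i], wander[i], u_quiesce[i], u_surface[i], v_depth[i]),
        )
        x_arr[i], y_arr[i] = state.x, state.y
        Tl_arr[i], Tr_arr[i] = T_left, T_right

    if info_out is not None:
        info_out["quiescent_from_s"] = state.quiescent_since
        info_out["final_T_B"] = state.T_B
    return TrackSeries(
        fish_id=fish_id,
        treatment=treatment,
        t=t,
        x=x_arr,
        y=y_arr,
        T_left=Tl_arr,
        T_right=Tr_arr,
        phase=phase_labels,
        termination_time=None,
    )


def generate_cohort(
    pop: PopulationParams,
    cfg: TrialConfig,
    seed,
) -> tuple[list, pd.DataFrame]:
    """Simulate a full cohort and return (tracks, ground-truth table).

    Fish ``i``'s baseline set point is Normal(mean_set_point, between_fish_sd²);
    each phase's realized set point adds Normal(0, within_fish_sd²) wobble.
    Treated fish ("h2s") have ``treatment_shift`` subtracted from the gas- and
    test-phase set points, the log-speed shift and quiescence hazard applied
    from gas onset, and per-frame surfacing odds raised by the H2S term.

    The truth table carries the generative parameters for parameter-recovery
    checks: baseline and realized per-phase set points, escape thresholds and
    the realized quiescence onset (if any).
    """
    n_total = pop.n_control + pop.n_treated
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_total + 1)
    pop_rng = np.random.default_rng(children[0])
    baselines = pop_rng.normal(pop.mean_set_point, pop.between_fish_sd, n_total)
    wobble = pop_rng.normal(0.0, pop.within_fish_sd, (n_total, len(PHASES)))

    base_params = FishAgentParams()
    tracks = []
    rows = []
    for i in range(n_total):
        treated = i >= pop.n_control
        label = "h2s" if treated else "control"
        fish_id = f"{label}_{(i - pop.n_control if treated else i):02d}"
        hazard = (
            pop.quiescence_hazard_treated
            if treated
            else pop.quiescence_hazard_control
        )
        overrides: dict[str, dict] = {}
        sp_by_phase = {}
        for j, ph in enumerate(PHASES):
            sp = baselines[i] + wobble[i, j]
            ov: dict = {"set_point": sp, "quiescence_hazard": 0.0}
            if ph in ("gas", "test"):
                if treated:
                    sp -= pop.treatment_shift
                    ov["set_point"] = sp
                    ov["speed_log_mean"] = (
                        base_params.speed_log_mean + pop.treatment_speed_shift
                    )
                    ov["h2s_on"] = True
                ov["quiescence_hazard"] = hazard
            overrides[ph] = ov
            sp_by_phase[ph] = sp
        info: dict = {}
        track = simulate_trial(
            cfg,
            base_params,
            children[i + 1],
            fish_id=fish_id,
            treatment=label,
            phase_overrides=overrides,
            info_out=info,
        )
        tracks.append(track)
        rows.append(
            {
                "fish_id": fish_id,
                "treatment": label,
                "set_point_C": baselines[i],
                "delta_U": base_params.delta_upper,
                "delta_L": base_params.delta_lower,
                "quiescent_from_s": info["quiescent_from_s"],
                "set_point_ramping_C": sp_by_phase["ramping"],
                "set_point_test_C": sp_by_phase["test"],
            }
        )
    return tracks, pd.DataFrame(rows)


#: The surfacing assay's 2x2 design: six fish per combination of
#: {0, 0.02 % H2S} x {21, 28 °C}, 60 min of 1 Hz frames each.
DEFAULT_ASR_DESIGN = [
    (0.0, 21.0, 6, 3600),
    (0.0, 28.0, 6, 3600),
    (0.02, 21.0, 6, 3600),
    (0.02, 28.0, 6, 3600),
]

#: Logit-linear coefficients (intercept, H2S, warm-temperature, interaction):
#: 2 % baseline surfacing, 17-fold odds increase under H2S, 3.5-fold with
#: warm water, no interaction.
DEFAULT_ASR_COEFFICIENTS = (
    math.log(0.02 / 0.98),
    math.log(17.0),
    math.log(3.5),
    0.0,
)


def generate_asr(
    design=DEFAULT_ASR_DESIGN,
    coefficients=DEFAULT_ASR_COEFFICIENTS,
    seed=0,
) -> list[ASRTrial]:
    """Generate surfacing-frame counts for the 2x2 H2S x temperature assay.

    Each fish's surfacing count is Binomial(n_frames, p) with
    ``logit p = b0 + b_h2s*1[h2s>0] + b_temp*1[warm] + b_int*1[both]``, where
    "warm" means a water temperature above ``SURFACE_TEMP_SPLIT`` (i.e. the
    28 °C level of the default design).
    """
    b0, bh, bt, bi = coefficients
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    trials: list[ASRTrial] = []
    for h2s, temp, n_fish, n_frames in design:
        if n_frames <= 0:
            raise ValueError("n_frames must be positive")
        ih = 1.0 if h2s > 0 else 0.0
        it = 1.0 if temp > SURFACE_TEMP_SPLIT else 0.0
        eta = b0 + bh * ih + bt * it + bi * ih * it
        if not math.isfinite(eta):
            raise ValueError("surfacing probability outside (0, 1)")
        p = 1.0 / (1.0 + math.exp(-eta))
        if not 0.0 < p < 1.0:
            raise ValueError("surfacing probability outside (0, 1)")
        counts = rng.binomial(n_frames, p, size=n_fish)
        for k in range(n_fish):
            trials.append(
                ASRTrial(
                    fish_id=f"asr_h{h2s:g}_t{temp:g}_{k:02d}",
                    h2s_pct=h2s,
                    water_temp=temp,
                    n_frames=int(n_frames),
                    n_surface_frames=int(counts[k]),
                )
            )
    return trials
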