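"""Behavioural metrics derived from shuttlebox tracks.

Reconstructs body temperature with the one-step thermal-lag recurrence,
detects midline crossings (shuttles) with optional hysteresis, and computes
the per-phase summary metrics: mean body temperature, side preference,
shuttle rate, lower/upper escape temperatures (LET/UET), mean log swim
velocity and the fraction of samples at the surface (aquatic surface
respiration, ASR).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .params import PHASES, TrackSeries

__all__ = [
    "BodyTempSeries",
    "ShuttleEvent",
    "BehaviourSummary",
    "body_temperature",
    "detect_shuttles",
    "side_preference",
    "escape_temperatures",
    "swim_velocity",
    "asr_fraction",
    "summarize",
    "summaries_to_frame",
    "summaries_from_frame",
]

SUMMARY_COLUMNS = [
    "fish_id",
    "treatment",
    "phase",
    "mean_TB_C",
    "side_pref",
    "shuttle_rate_per_min",
    "LET_C",
    "UET_C",
    "mean_log_vel",
    "asr_fraction",
    "terminated_s",
]


@dataclass
class BodyTempSeries:
    """Reconstructed body temperature at each track sample.

    ``occupied_side`` is -1 for the left (cold) and +1 for the right (warm)
    chamber, with samples at exactly x = 0 keeping the previous side.
    """

    fish_id: str
    t: np.ndarray
    T_B: np.ndarray
    occupied_side: np.ndarray


@dataclass(frozen=True)
class ShuttleEvent:
    """One midline crossing.

    ``direction`` is ``"LR"`` (left to right, leaving the cold side) or
    ``"RL"``; ``pre_shuttle_T_B`` is the body temperature at the last sample
    before the crossing — the escape temperature of that shuttle.
    """

    t: float
    direction: str
    pre_shuttle_T_B: float
    index: int


@dataclass
class BehaviourSummary:
    """Per-fish, per-phase derived metrics (NaN where undefined)."""

    fish_id: str
    treatment: str
    phase: str
    mean_T_B: float
    side_preference: float
    shuttle_rate: float
    LET: float
    UET: float
    mean_log_velocity: float
    asr_fraction: float
    terminated_s: float = math.nan


def _occupied_sides(x: np.ndarray, initial_side: int = -1) -> np.ndarray:
    """Side occupied at each sample (-1 left, +1 right); x == 0 keeps the
    previous side, and a leading run of zeros takes ``initial_side``."""
    s = np.sign(x).astype(np.int8)
    if np.all(s != 0):
        return s
    idx = np.where(s != 0, np.arange(len(s)), -1)
    np.maximum.accumulate(idx, out=idx)
    out = np.where(idx >= 0, s[np.maximum(idx, 0)], np.int8(initial_side))
    return out.astype(np.int8)


def body_temperature(track: TrackSeries) -> BodyTempSeries:
    """Body temperature via the thermal-lag recurrence.

    ``T_B(0)`` equals the occupied chamber's temperature at the first sample;
    thereafter ``T_B(t) = (T_occupied(t) + T_B(t-1)) / 2``.  Small fish
    equilibrate fast, so the body temperature is a half-life-one-sample
    geometric average of the water the fish has recently occupied.
    """
    if len(track) == 0:
        raise ValueError("empty track")
    sides = _occupied_sides(track.x)
    T_occ = np.where(sides < 0, track.T_left, track.T_right)
    # T_B(t) = 0.5*T_occ(t) + 0.5*T_B(t-1) is a first-order IIR filter;
    # the initial condition makes T_B(0) = T_occ(0) exactly.
    zi = np.array([0.5 * T_occ[0]])
    T_B, _ = lfilter([0.5], [1.0, -0.5], T_occ, zi=zi)
    return BodyTempSeries(
        fish_id=track.fish_id, t=track.t, T_B=T_B, occupied_side=sides
    )


def detect_shuttles(
    track: TrackSeries,
    deadband: float = 0.0,
    body_temp: BodyTempSeries | None = None,
) -> tuple[list[ShuttleEvent], dict[str, float]]:
    """Detect midline crossings and per-phase shuttle rates.

    With ``deadband`` 0 an event is any sign change of x between consecutive
    samples (samples at exactly 0 keep the previous side).  With a positive
    deadband ``d`` the crossing only counts once |x| exceeds d on the new side
    (hysteresis against midline jitter).  ``shuttle_rate`` is events per
    minute of phase actually observed.
    """
    if deadband < 0:
        raise ValueError("deadband must be >= 0")
    if len(track) == 0:
        raise ValueError("empty track")
    if body_temp is None:
        body_temp = body_temperature(track)
    x = track.x
    if deadband == 0.0:
        committed = _occupied_sides(x)
    else:
        s = np.where(np.abs(x) > deadband, np.sign(x), 0).astype(np.int8)
        committed = _occupied_sides(s.astype(float))
    change = np.flatnonzero(committed[1:] != committed[:-1]) + 1
    events = [
        ShuttleEvent(
            t=float(track.t[i]),
            direction="LR" if committed[i] > 0 else "RL",
            pre_shuttle_T_B=float(body_temp.T_B[i - 1]),
            index=int(i),
        )
        for i in change
    ]
    dt = float(track.t[1] - track.t[0]) if len(track) > 1 else 1.0
    rates: dict[str, float] = {}
    for ph in PHASES:
        mask = track.phase == ph
        n_samp = int(mask.sum())
        if n_samp == 0:
            continue
        minutes = n_samp * dt / 60.0
        n_ev = sum(1 for e in events if track.phase[e.index] == ph)
        rates[ph] = n_ev / minutes
    return events, rates


def side_preference(track: TrackSeries, phase: str) -> float:
    """Side-preference index ``2*(0.5 - Time_{x<0}/Time_total)`` over a phase.

    -1 means all time on the left (cold) side, +1 all time on the right.
    """
    mask = track.phase == phase
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"phase {phase!r} has no samples")
    frac_left = float(np.mean(track.x[mask] < 0))
    return 2.0 * (0.5 - frac_left)


def escape_temperatures(
    events: list[ShuttleEvent],
) -> tuple[float, float]:
    """(LET, UET) from a list of shuttle events; NaN where undefined.

    LET is the mean pre-shuttle body temperature over left-to-right events
    (the fish leaving the cold side), UET the mean over right-to-left events.
    With no events in a direction the corresponding value is NaN — flagged,
    never fabricated.
    """
    lr = [e.pre_shuttle_T_B for e in events if e.direction == "LR"]
    rl = [e.pre_shuttle_T_B for e in events if e.direction == "RL"]
    let = float(np.mean(lr)) if lr else math.nan
    uet = float(np.mean(rl)) if rl else math.nan
    return let, uet


def swim_velocity(
    track: TrackSeries,
    phase: str,
    floor: float = 0.01,
    box_height: float = 20.0,
) -> float:
    """Mean log swim speed (log cm/s) over a phase.

    Speed is the per-sample Euclidean displacement of (x, y*box_height)
    divided by the sampling interval; speeds below ``floor`` cm/s are raised
    to the floor before the log so stationary samples stay finite.
    """
    if floor <= 0:
        raise ValueError("velocity floor must be positive")
    mask = track.phase == phase
    idx = np.flatnonzero(mask)
    if len(idx) < 2:
        raise ValueError(f"phase {phase!r} needs at least 2 samples")
    dt = float(track.t[idx[1]] - track.t[idx[0]])
    dx = np.diff(track.x[idx])
    dy = np.diff(track.y[idx]) * box_height
    speed = np.hypot(dx, dy) / dt
    return float(np.mean(np.log(np.maximum(speed, floor))))


def asr_fraction(
    track: TrackSeries, surface_threshold: float = 0.9, phase: str | None = None
) -> float:
    """Fraction of samples with normalized depth above ``surface_threshold``."""
    if len(track) == 0:
        raise ValueError("empty track")
    y = track.y if phase is None else track.y[track.phase == phase]
    if len(y) == 0:
        raise ValueError(f"phase {phase!r} has no samples")
    return float(np.mean(y > surface_threshold))


def summarize(
    track: TrackSeries,
    deadband: float = 0.0,
    surface_threshold: float = 0.9,
    velocity_floor: float = 0.01,
    box_height: float = 20.0,
) -> list[BehaviourSummary]:
    """One :class:`BehaviourSummary` per phase present in the track.

    Samples at/after ``termination_time`` are excluded; the termination time
    itself is recorded on every summary row so partial phases are flagged
    rather than silently mixed with complete ones.
    """
    tr = track.truncated()
    if len(tr) == 0:
        raise ValueError("track empty after termination truncation")
    bt = body_temperature(tr)
    events, rates = detect_shuttles(tr, deadband=deadband, body_temp=bt)
    term = math.nan if track.termination_time is None else float(track.termination_time)
    out: list[BehaviourSummary] = []
    for ph in PHASES:
        mask = tr.phase == ph
        if not mask.any():
            continue
        ev_ph = [e for e in events if tr.phase[e.index] == ph]
        let, uet = escape_temperatures(ev_ph)
        try:
            mlv = swim_velocity(tr, ph, floor=velocity_floor, box_height=box_height)
        except ValueError:
            mlv = math.nan
        out.append(
            BehaviourSummary(
                fish_id=tr.fish_id,
                treatment=tr.treatment,
                phase=ph,
                mean_T_B=float(np.mean(bt.T_B[mask])),
                side_preference=side_preference(tr, ph),
                shuttle_rate=rates[ph],
                LET=let,
                UET=uet,
                mean_log_velocity=mlv,
                asr_fraction=asr_fraction(tr, surface_threshold, phase=ph),
                terminated_s=term,
            )
        )
    return out


def summaries_to_frame(summaries: list[BehaviourSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "fish_id": [s.fish_id for s in summaries],
            "treatment": [s.treatment for s in summaries],
            "phase": [s.phase for s in summaries],
            "mean_TB_C": [s.mean_T_B for s in summaries],
            "side_pref": [s.side_preference for s in summaries],
            "shuttle_rate_per_min": [s.shuttle_rate for s in summaries],
            "LET_C": [s.LET for s in summaries],
            "UET_C": [s.UET for s in summaries],
            "mean_log_vel": [s.mean_log_velocity for s in summaries],
            "asr_fraction": [s.asr_fraction for s in summaries],
            "terminated_s": [s.terminated_s for s in summaries],
        }
    )[SUMMARY_COLUMNS]


def summaries_from_frame(df: pd.DataFrame) -> list[BehaviourSummary]:
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary frame missing columns: {missing}")
    return [
        BehaviourSummary(
            fish_id=str(r.fish_id),
            treatment=str(r.treatment),
            phase=str(r.phase),
            mean_T_B=float(r.mean_TB_C),
            side_preference=float(r.side_pref),
            shuttle_rate=float(r.shuttle_rate_per_min),
            LET=float(r.LET_C),
            UET=float(r.UET_C),
            mean_log_velocity=float(r.mean_log_vel),
            asr_fraction=float(r.asr_fraction),
            terminated_s=float(r.terminated_s),
        )
        for r in df.itertuples()
    ]
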