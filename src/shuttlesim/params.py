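"""Domain types for the virtual shuttlebox.

A dynamic shuttlebox is a two-chamber arena in which the temperature of both
chambers ramps up while the fish occupies the warm (right) side and down while
it occupies the cold (left) side, holding a fixed offset between chambers.  A
thermoregulating fish must shuttle back and forth to hold its preferred body
temperature, so the oscillation band of its reconstructed body temperature
reveals the thermal set point it defends.

These dataclasses describe the trial protocol (:class:`TrialConfig`), the
instantaneous chamber state (:class:`ChamberState`), the generative behaviour
parameters of a simulated fish (:class:`FishAgentParams`), a cohort design
(:class:`PopulationParams`), the raw per-second track of one trial
(:class:`TrackSeries`) and one surfacing-assay observation (:class:`ASRTrial`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PHASES",
    "TrialConfig",
    "ChamberState",
    "FishAgentParams",
    "PopulationParams",
    "TrackSeries",
    "ASRTrial",
    "TRACK_COLUMNS",
]

#: Trial phases in protocol order.  The controller is inactive during
#: habituation and active afterwards.
PHASES = ("habituation", "ramping", "gas", "test")

#: Column order of the track CSV interchange format.
TRACK_COLUMNS = [
    "fish_id",
    "treatment",
    "phase",
    "t_s",
    "x_cm",
    "y_norm",
    "T_left_C",
    "T_right_C",
]


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


@dataclass(frozen=True)
class TrialConfig:
    """Protocol configuration for one shuttlebox trial.

    Parameters
    ----------
    sample_rate : float
        Sampling frequency in Hz (default 1).
    phase_durations : mapping
        Phase length in minutes for each of ``habituation``, ``ramping``,
        ``gas`` and ``test`` (defaults 60 / 120 / 30 / 240).
    chamber_offset : float
        Constant temperature difference ``T_right - T_left`` in °C (right
        chamber warmer, default 3.0).
    ramp_rate : float
        Ramping speed in °C per minute (default 0.5): cooling while the fish
        occupies the left side, warming while it occupies the right side.
    temp_limits : (float, float)
        Hard limits in °C that both chamber temperatures must respect
        (default (15, 35)).
    housing_temp : float
        Housing/acclimation temperature in °C (default 27).
    initial_left_temp : float or None
        Left-chamber temperature at trial start; ``None`` means
        ``housing_temp - 1.5`` as in the protocol.
    half_width_cm : float
        Half-width of the arena: each chamber spans ``[0, half_width_cm]``
        distance from the midline (x = 0, +x to the right).
    box_height_cm : float
        Water depth used to convert normalized depth y in [0, 1] to cm for
        velocity computation.
    surface_threshold : float
        Normalized depth above which a sample counts as "at the surface"
        (default 0.9; y = 1 is the surface).
    """

    sample_rate: float = 1.0
    phase_durations: Mapping[str, float] = field(
        default_factory=lambda: {
            "habituation": 60.0,
            "ramping": 120.0,
            "gas": 30.0,
            "test": 240.0,
        }
    )
    chamber_offset: float = 3.0
    ramp_rate: float = 0.5
    temp_limits: tuple[float, float] = (15.0, 35.0)
    housing_temp: float = 27.0
    initial_left_temp: float | None = None
    half_width_cm: float = 15.0
    box_height_cm: float = 20.0
    surface_threshold: float = 0.9

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.ramp_rate <= 0:
            raise ValueError("ramp_rate must be positive")
        lo, hi = self.temp_limits
        if not lo < hi:
            raise ValueError("temp_limits must satisfy lower < upper")
        if self.chamber_offset < 0:
            raise ValueError("chamber_offset must be >= 0")
        if self.chamber_offset > hi - lo:
            raise ValueError("chamber_offset exceeds the temperature range")
        unknown = set(self.phase_durations) - set(PHASES)
        if unknown:
            raise ValueError(f"unknown phase names: {sorted(unknown)}")
        for ph in PHASES:
            if self.phase_durations.get(ph, 0.0) < 0:
                raise ValueError(f"phase duration for {ph!r} must be >= 0")
        t0 = self.left_start_temp
        if not lo <= t0 <= hi - self.chamber_offset:
            raise ValueError(
                "initial_left_temp must keep both chambers within temp_limits"
            )
        if self.half_width_cm <= 0 or self.box_height_cm <= 0:
            raise ValueError("box dimensions must be positive")
        if not 0.0 < self.surface_threshold < 1.0:
            raise ValueError("surface_threshold must be in (0, 1)")

    @property
    def left_start_temp(self) -> float:
        """Left-chamber temperature at trial start (°C)."""
        if self.initial_left_temp is None:
            return self.housing_temp - 1.5
        return self.initial_left_temp

    @property
    def dt(self) -> float:
        """Sampling interval in seconds."""
        return 1.0 / self.sample_rate

    def phase_samples(self) -> dict[str, int]:
        """Number of samples per phase, in protocol order."""
        return {
            ph: int(round(self.phase_durations.get(ph, 0.0) * 60.0 * self.sample_rate))
            for ph in PHASES
        }

    def n_samples(self) -> int:
        return sum(self.phase_samples().values())


@dataclass
class ChamberState:
    """Instantaneous state of the two-chamber thermal controller.

    ``T_right - T_left`` equals the configured offset at all times; both
    temperatures stay within the configured limits.
    """

    t: float
    T_left: float
    T_right: float
    controller_active: bool = True

    def validate(self, cfg: TrialConfig) -> None:
        lo, hi = cfg.temp_limits
        if abs((self.T_right - self.T_left) - cfg.chamber_offset) > 1e-9:
            raise ValueError("chamber offset invariant violated")
        if self.T_left < lo - 1e-9 or self.T_right > hi + 1e-9:
            raise ValueError("chamber temperature outside limits")


@dataclass(frozen=True)
class FishAgentParams:
    """Generative thermoregulation parameters of one simulated fish.

    The agent defends ``set_point`` with a dual-threshold rule: body
    temperature rising ``delta_upper`` above the set point triggers a shuttle
    to the cold side, falling ``delta_lower`` below it a shuttle to the warm
    side; between the thresholds the fish wanders within its current chamber.
    Per-second displacement magnitudes are log-normal.  ``quiescence_hazard``
    is the per-second probability of permanently ceasing to shuttle (absorbing
    state, fish confined to its current side).  The three ``surface_logit_*``
    terms give per-frame surfacing log-odds: baseline, additive shift under
    H2S exposure, and additive shift when the body temperature is warm
    (above the midpoint of the surfacing assay's two temperatures, 24.5 °C).
    """

    set_point: float = 27.3
    delta_upper: float = 1.5
    delta_lower: float = 1.5
    speed_log_mean: float = math.log(2.0)  # log cm/s
    speed_log_sd: float = 0.5
    quiescence_hazard: float = 0.0
    surface_logit_base: float = _logit(0.02)
    surface_logit_h2s: float = math.log(17.0)
    surface_logit_temp: float = math.log(3.5)

    def __post_init__(self) -> None:
        for name in ("set_point", "speed_log_mean", "speed_log_sd",
                     "delta_upper", "delta_lower", "quiescence_hazard",
                     "surface_logit_base", "surface_logit_h2s",
                     "surface_logit_temp"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.delta_upper <= 0 or self.delta_lower <= 0:
            raise ValueError("escape thresholds must be positive")
        if not 0.0 <= self.quiescence_hazard <= 1.0:
            raise ValueError("quiescence_hazard must be in [0, 1]")
        if self.speed_log_sd < 0:
            raise ValueError("speed_log_sd must be >= 0")

    def with_(self, **kw) -> "FishAgentParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class PopulationParams:
    """Cohort design: between/within-fish set-point variation and H2S effects.

    Fish ``i``'s baseline set point is Normal(``mean_set_point``,
    ``between_fish_sd``²); each phase adds independent Normal(0,
    ``within_fish_sd``²) wobble.  Treated fish have ``treatment_shift`` °C
    subtracted from the gas- and test-phase set points (anapyrexia),
    ``treatment_speed_shift`` added to the log swim speed from gas onset, and
    a distinct quiescence hazard.
    """

    mean_set_point: float = 27.3
    between_fish_sd: float = 1.5
    within_fish_sd: float = 1.4
    treatment_shift: float = 6.0
    treatment_speed_shift: float = 0.15
    n_control: int = 20
    n_treated: int = 17
    quiescence_hazard_control: float = 0.0
    quiescence_hazard_treated: float = 1e-5

    def __post_init__(self) -> None:
        if self.between_fish_sd < 0 or self.within_fish_sd < 0:
            raise ValueError("set-point standard deviations must be >= 0")
        if self.n_control < 0 or self.n_treated < 0:
            raise ValueError("group sizes must be >= 0")
        for name in ("quiescence_hazard_control", "quiescence_hazard_treated"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class TrackSeries:
    """Per-second trajectory and chamber temperatures for one fish.

    x is signed distance from the midline in cm (+x to the right); y is
    normalized depth in [0, 1] with 1 at the surface.  ``termination_time``
    marks pre-emptive removal (seconds since trial start) or ``None``.
    """

    fish_id: str
    treatment: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    T_left: np.ndarray
    T_right: np.ndarray
    phase: np.ndarray
    termination_time: float | None = None

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("x", "y", "T_left", "T_right", "phase"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name!r} length mismatch")

    def __len__(self) -> int:
        return len(self.t)

    def validate(self, cfg: TrialConfig) -> None:
        """Check invariants against the generating config."""
        dt = cfg.dt
        if not np.allclose(np.diff(self.t), dt):
            raise ValueError("timestamps must be uniformly spaced at 1/sample_rate")
        lo, hi = cfg.temp_limits
        if np.any(np.abs((self.T_right - self.T_left) - cfg.chamber_offset) > 1e-9):
            raise ValueError("chamber offset invariant violated")
        if np.any(self.T_left < lo - 1e-9) or np.any(self.T_right > hi + 1e-9):
            raise ValueError("chamber temperature outside limits")
        if np.any(np.abs(self.x) > cfg.half_width_cm + 1e-9):
            raise ValueError("x outside arena")

    def truncated(self) -> "TrackSeries":
        """Drop samples at/after the termination time, if any."""
        if self.termination_time is None:
            return self
        keep = self.t < self.termination_time
        return TrackSeries(
            fish_id=self.fish_id,
            treatment=self.treatment,
            t=self.t[keep],
            x=self.x[keep],
            y=self.y[keep],
            T_left=self.T_left[keep],
            T_right=self.T_right[keep],
            phase=self.phase[keep],
            termination_time=self.termination_time,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fish_id": self.fish_id,
                "treatment": self.treatment,
                "phase": self.phase,
                "t_s": self.t,
                "x_cm": self.x,
                "y_norm": self.y,
                "T_left_C": self.T_left,
                "T_right_C": self.T_right,
            }
        )[TRACK_COLUMNS]

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, termination_time: float | None = None
    ) -> "TrackSeries":
        missing = [c for c in TRACK_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"track frame missing columns: {missing}")
        fish_ids = df["fish_id"].unique()
        if len(fish_ids) != 1:
            raise ValueError("from_frame expects a single fish; use split on fish_id")
        return cls(
            fish_id=str(fish_ids[0]),
            treatment=str(df["treatment"].iloc[0]),
            t=df["t_s"].to_numpy(dtype=float),
            x=df["x_cm"].to_numpy(dtype=float),
            y=df["y_norm"].to_numpy(dtype=float),
            T_left=df["T_left_C"].to_numpy(dtype=float),
            T_right=df["T_right_C"].to_numpy(dtype=float),
            phase=df["phase"].to_numpy(dtype=object),
            termination_time=termination_time,
        )


@dataclass(frozen=True)
class ASRTrial:
    """Surfacing-frame counts for one fish in the 2x2 H2S x temperature assay."""

    fish_id: str
    h2s_pct: float
    water_temp: float
    n_frames: int
    n_surface_frames: int

    def __post_init__(self) -> None:
        if self.n_frames <= 0:
            raise ValueError("n_frames must be positive")
        if not 0 <= self.n_surface_frames <= self.n_frames:
            raise ValueError("n_surface_frames must be in [0, n_frames]")

    @property
    def fraction(self) -> float:
        return self.n_surface_frames / self.n_frames


def asr_trials_to_frame(trials: list[ASRTrial]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "fish_id": [tr.fish_id for tr in trials],
            "h2s_pct": [tr.h2s_pct for tr in trials],
            "temp_C": [tr.water_temp for tr in trials],
            "n_frames": [tr.n_frames for tr in trials],
            "n_surface": [tr.n_surface_frames for tr in trials],
        }
    )


def asr_trials_from_frame(df: pd.DataFrame) -> list[ASRTrial]:
    required = ["fish_id", "h2s_pct", "temp_C", "n_frames", "n_surface"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"ASR frame missing columns: {missing}")
    return [
        ASRTrial(
            fish_id=str(r.fish_id),
            h2s_pct=float(r.h2s_pct),
            water_temp=float(r.temp_C),
            n_frames=int(r.n_frames),
            n_surface_frames=int(r.n_surface),
        )
        for r in df.itertuples()
    ]
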