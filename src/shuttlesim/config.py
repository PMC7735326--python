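"""Run configuration: a single YAML file describing a full pipeline run.

Blocks mirror the pipeline stages::

    trial:       # TrialConfig fields (protocol)
    population:  # PopulationParams fields (cohort design)
    metrics:     # deadband_cm, surface_threshold, velocity_floor
    inference:   # n_boot, n_perm, rho, basis_dim, smooth_bin_s
    asr:         # design rows + logit coefficients for the surfacing assay
    output:      # directory, log level

Every key is optional (documented defaults fill in); unknown keys are
rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .params import PopulationParams, TrialConfig
from .sim import DEFAULT_ASR_COEFFICIENTS, DEFAULT_ASR_DESIGN

__all__ = ["MetricsOptions", "InferenceOptions", "AsrOptions", "OutputOptions",
           "RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class MetricsOptions:
    deadband_cm: float = 0.0
    surface_threshold: float = 0.9
    velocity_floor: float = 0.01

    def __post_init__(self) -> None:
        if self.deadband_cm < 0:
            raise ValueError("deadband_cm must be >= 0")
        if not 0 < self.surface_threshold < 1:
            raise ValueError("surface_threshold must be in (0, 1)")
        if self.velocity_floor <= 0:
            raise ValueError("velocity_floor must be positive")


@dataclass(frozen=True)
class InferenceOptions:
    n_boot: int = 1000
    n_perm: int = 1000
    rho: float = 0.95
    basis_dim: int = 20
    #: bin width (seconds) for averaging body-temperature series before the
    #: difference smoother, and for the ZIP shuttle-count bins (1 min).
    smooth_bin_s: float = 60.0
    zip_bin_s: float = 60.0

    def __post_init__(self) -> None:
        if self.n_boot < 0 or self.n_perm < 0:
            raise ValueError("bootstrap/permutation counts must be >= 0")
        if not -1 < self.rho < 1:
            raise ValueError("rho must be in (-1, 1)")
        if self.basis_dim < 4:
            raise ValueError("basis_dim must be >= 4")
        if self.smooth_bin_s <= 0 or self.zip_bin_s <= 0:
            raise ValueError("bin widths must be positive")


@dataclass(frozen=True)
class AsrOptions:
    design: tuple = tuple(DEFAULT_ASR_DESIGN)
    coefficients: tuple = DEFAULT_ASR_COEFFICIENTS

    def __post_init__(self) -> None:
        if len(self.coefficients) != 4:
            raise ValueError("coefficients must be (b0, b_h2s, b_temp, b_int)")
        for row in self.design:
            if len(row) != 4:
                raise ValueError("design rows are (h2s, temp, n_fish, n_frames)")
            if row[2] <= 0 or row[3] <= 0:
                raise ValueError("design n_fish and n_frames must be positive")
        for c in self.coefficients:
            if not math.isfinite(c):
                raise ValueError("coefficients must be finite")


@dataclass(frozen=True)
class OutputOptions:
    directory: str = "shuttlesim_out"
    log_level: str = "info"

    def __post_init__(self) -> None:
        if self.log_level not in ("debug", "info", "warning"):
            raise ValueError("log_level must be debug, info or warning")


@dataclass(frozen=True)
class RunConfig:
    trial: TrialConfig = field(default_factory=TrialConfig)
    population: PopulationParams = field(default_factory=PopulationParams)
    metrics: MetricsOptions = field(default_factory=MetricsOptions)
    inference: InferenceOptions = field(default_factory=InferenceOptions)
    asr: AsrOptions = field(default_factory=AsrOptions)
    output: OutputOptions = field(default_factory=OutputOptions)


_BLOCKS = {
    "trial": TrialConfig,
    "population": PopulationParams,
    "metrics": MetricsOptions,
    "inference": InferenceOptions,
    "asr": AsrOptions,
    "output": OutputOptions,
}


def _build(cls, block: dict, block_name: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - names
    if unknown:
        raise ValueError(
            f"unknown key(s) in {block_name!r} block: {sorted(unknown)}"
        )
    kwargs = dict(block)
    # YAML gives lists; dataclass fields that are tuples in defaults accept
    # sequences as-is except TrialConfig.temp_limits which must be a tuple.
    if cls is TrialConfig and "temp_limits" in kwargs:
        kwargs["temp_limits"] = tuple(kwargs["temp_limits"])
    if cls is AsrOptions:
        if "design" in kwargs:
            kwargs["design"] = tuple(tuple(r) for r in kwargs["design"])
        if "coefficients" in kwargs:
            kwargs["coefficients"] = tuple(kwargs["coefficients"])
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Load and validate a run configuration; missing keys take defaults.

    Raises ``ValueError`` naming the offending key for unknown keys or
    out-of-range values.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping of blocks")
    unknown = set(data) - set(_BLOCKS)
    if unknown:
        raise ValueError(f"unknown config block(s): {sorted(unknown)}")
    built = {}
    for name, cls in _BLOCKS.items():
        block = data.get(name, {})
        if block is None:
            block = {}
        if not isinstance(block, dict):
            raise ValueError(f"config block {name!r} must be a mapping")
        built[name] = _build(cls, block, name)
    return RunConfig(**built)


def _plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return [_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    return obj


def config_to_dict(cfg: RunConfig) -> dict:
    return _plain(cfg)


def save_config(cfg: RunConfig, path) -> None:
    """Write a config back to YAML; load_config(save_config(c)) == c."""
    Path(path).write_text(
        yaml.safe_dump(config_to_dict(cfg), sort_keys=True)
    )
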