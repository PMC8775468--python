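"""Pipeline configuration: one validated schema for every stage.

Numeric defaults that come from the analysis protocol are centralized
here: correlation threshold 0.3, lag range W = 10 frames, network bursts
on >= 4 electrodes with <= 100 ms gaps.  Unknown keys in a config file are
rejected rather than ignored, so typos fail loudly before any stage runs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .bursts import DEFAULT_MAX_GAP_MS, DEFAULT_MIN_ELECTRODES
from .metrics import DEFAULT_CONTACT_SLACK
from .network import DEFAULT_DETREND_S, DEFAULT_LAG_RANGE, DEFAULT_RHO_THR


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclass
class SimulateSection:
    n_cells: int = 45
    field_size: list[float] = field(default_factory=lambda: [1000.0, 1000.0])
    n_frames: int = 3000
    transient_rate: float = 1.34  # events/min
    transient_duration: float = 12.0  # s
    transient_amplitude: float = 10.0
    noise_sd: float = 1.0
    inactive_fraction: float = 0.4
    planted_edges: list = field(default_factory=list)  # [src, dst, lag, p]


@dataclass
class DetectSection:
    threshold_multiplier: float = 1.0
    min_duration_s: float = 3.5
    smooth_s: float = 1.0
    deviation_mode: str = "std"


@dataclass
class SegmentSection:
    enabled: bool = False
    image_shape: list[int] = field(default_factory=lambda: [256, 256])
    pixel_threshold_multiplier: float = 1.5
    min_voxels: int = 20
    smoothing_sigma: float = 2.0
    min_seed_distance: int = 5


@dataclass
class NetworkSection:
    detrend_s: float = DEFAULT_DETREND_S
    lag_range: int = DEFAULT_LAG_RANGE  # W, frames
    rho_thr: float = DEFAULT_RHO_THR
    mode: str = "directed"
    strict_lag: bool = False


@dataclass
class MetricsSection:
    contact_slack: float = DEFAULT_CONTACT_SLACK


@dataclass
class MeaSection:
    enabled: bool = True
    n_electrodes: int = 60
    duration_min: float = 10.0
    n_bursts: int = 36
    electrodes_per_burst: int = 10
    spikes_per_electrode: int = 9
    jitter_ms: float = 1.0
    background_rate: float = 0.02  # spikes/s per electrode, asynchronous
    min_electrodes: int = DEFAULT_MIN_ELECTRODES
    max_gap_ms: float = DEFAULT_MAX_GAP_MS


@dataclass
class PipelineConfig:
    """Validated parameters for a full pipeline run."""

    seed: int = 0
    frame_rate: float | None = None  # frames/s; required, no default
    um_per_pixel: float = 4.0
    simulate: SimulateSection = field(default_factory=SimulateSection)
    detect: DetectSection = field(default_factory=DetectSection)
    segment: SegmentSection = field(default_factory=SegmentSection)
    network: NetworkSection = field(default_factory=NetworkSection)
    metrics: MetricsSection = field(default_factory=MetricsSection)
    mea: MeaSection = field(default_factory=MeaSection)

    def validate(self) -> "PipelineConfig":
        if self.frame_rate is None or not self.frame_rate > 0:
            raise ConfigError("frame_rate must be set to a positive value")
        if self.um_per_pixel <= 0:
            raise ConfigError("um_per_pixel must be positive")
        if self.network.mode not in ("directed", "undirected"):
            raise ConfigError("network.mode must be 'directed' or 'undirected'")
        if self.detect.deviation_mode not in ("std", "sem", "mad"):
            raise ConfigError("detect.deviation_mode must be std, sem or mad")
        return self

    def as_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "simulate": SimulateSection,
    "detect": DetectSection,
    "segment": SegmentSection,
    "network": NetworkSection,
    "metrics": MetricsSection,
    "mea": MeaSection,
}


def _build(cls, data: dict, where: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")
    return cls(**data)


def config_from_dict(data: dict) -> PipelineConfig:
    data = dict(data or {})
    sections = {}
    for name, cls in _SECTIONS.items():
        raw = data.pop(name, {})
        if not isinstance(raw, dict):
            raise ConfigError(f"section '{name}' must be a mapping")
        sections[name] = _build(cls, raw, f"section '{name}'")
    top = _build(PipelineConfig, data, "top level")
    for name, sec in sections.items():
        setattr(top, name, sec)
    return top.validate()


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    return config_from_dict(raw)
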