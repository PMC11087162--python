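"""Analysis configuration: every tunable of the recording -> latency pipeline."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .preprocess import FilterSpec

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    """Settings for the full analysis chain.

    Defaults reproduce the reference procedure: 50 Hz zero-phase notch +
    11-sample moving median on the motion channel, 90% peak-to-peak peak
    threshold, order-2 polynomial peak fit, 40%-60% gating window, 20%/80%
    edge thresholds with 5 ms debounce.
    """

    filter: FilterSpec = field(default_factory=FilterSpec)
    gate_open_phase: float = 0.40
    gate_close_phase: float = 0.60
    peak_threshold: float = 0.9
    fit_order: int = 2
    refine_per_cycle: bool = False
    edge_low_fraction: float = 0.2
    edge_high_fraction: float = 0.8
    debounce_ms: float = 5.0
    period_band: tuple = (1.0, 10.0)
    beam_search_window_s: float = 1.0

    def validate(self) -> None:
        if not 0 <= self.gate_open_phase < self.gate_close_phase <= 1:
            raise ConfigurationError("gate phases: need 0 <= open < close <= 1")
        if not 0 < self.peak_threshold < 1:
            raise ConfigurationError("peak_threshold: must lie in (0, 1)")
        if not 0 < self.edge_low_fraction < self.edge_high_fraction < 1:
            raise ConfigurationError("edge fractions: need 0 < low < high < 1")
        if self.fit_order < 2:
            raise ConfigurationError("fit_order: must be >= 2")
        if self.debounce_ms < 0:
            raise ConfigurationError("debounce_ms: must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["period_band"] = list(self.period_band)
        return d

    def config_hash(self) -> str:
        """Short stable hash of the effective configuration, for provenance."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        filt = d.pop("filter", {})
        if isinstance(filt, dict):
            filt = FilterSpec(**filt)
        if "period_band" in d:
            d["period_band"] = tuple(d["period_band"])
        cfg = cls(filter=filt, **d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path}: expected a mapping")
        return cls.from_dict(data)

    def with_overrides(self, **kwargs) -> "AnalysisConfig":
        """Copy with non-None keyword overrides applied (flags win over file)."""
        filt_fields = {f.name for f in dataclasses.fields(FilterSpec)}
        filt_kw = {k: v for k, v in kwargs.items() if k in filt_fields and v is not None}
        own_kw = {
            k: v for k, v in kwargs.items() if k not in filt_fields and v is not None
        }
        new_filter = dataclasses.replace(self.filter, **filt_kw)
        cfg = dataclasses.replace(self, filter=new_filter, **own_kw)
        cfg.validate()
        return cfg
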