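"""Run configuration: one flat object holding every stage parameter.

Defaults reproduce the documented analysis constants: 900-second segments,
98th-percentile capping, 95th-percentile normalization, 0.15 Hz respiratory
cutoff, 15-second event baseline, 5-minute CV window stepped every 30
seconds, ±30-second alignment window, and the ≥3-event inclusion rule.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml

from vasowave.errors import ConfigurationError
from vasowave.synthetic_data import SimConfig


@dataclass
class RunConfig:
    seed: int = 0
    n_nights: int = 3

    # pulse extraction
    grid_dt: float = 0.5
    hr_min_bpm: float = 40.0
    hr_max_bpm: float = 180.0
    prominence_frac: float = 0.3

    # preprocessing
    seg_len_s: float = 900.0
    max_masked_frac: float = 0.2
    accel_thresh: float = 0.1
    cap_pctl: float = 98.0
    norm_pctl: float = 95.0
    cutoff_hz: float = 0.15

    # markers
    baseline_s: float = 15.0
    depth_thresh: float = 0.15
    min_dur_s: float = 3.0
    window_s: float = 300.0
    step_s: float = 30.0

    # alignment and validation
    max_lag_s: float = 30.0
    min_events: int = 3
    min_pairs: int = 10
    correlation: str = "pearson"
    pairing_mode: str = "zero_fill"

    # overrides applied on top of SimConfig defaults for simulated nights
    simulate: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.correlation not in ("pearson", "spearman"):
            raise ConfigurationError(f"unknown correlation {self.correlation!r}")
        if self.pairing_mode not in ("zero_fill", "event_only"):
            raise ConfigurationError(f"unknown pairing_mode {self.pairing_mode!r}")
        if self.n_nights < 1:
            raise ConfigurationError("n_nights must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def sim_config(self, night_index: int, **overrides) -> SimConfig:
        """SimConfig for one simulated night, seeded deterministically."""
        params = dict(self.simulate)
        params.update(overrides)
        params.setdefault("seed", self.seed * 10007 + night_index)
        return SimConfig(**params)
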