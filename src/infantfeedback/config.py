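"""Run configuration: defaults < config file < command-line flags.

The config file is flat ``key = value`` text (``#`` comments allowed); keys
mirror the engine and analysis parameters.  The merged configuration is
serialized into every output report for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

from .errors import SchemaError
from .feedback_engine import FeedbackConfig, ThresholdConfig
from .imu_io import LIMBS

__all__ = ["RunConfig", "parse_config_file"]


@dataclass
class RunConfig:
    """Every tunable the engine, simulator and analyses expose."""

    window_s: float = 5.0
    w_max: float = 0.5
    w_mean: float = 0.5
    epsilon: float = 0.8
    ramp_up_s: float = 1.0
    ramp_down_s: float = 2.0
    p_active: float = 0.68
    n_sessions: int = 5
    session_duration_s: float = 180.0
    controlling_limbs: tuple[str, ...] = LIMBS
    min_coverage: float = 0.95
    max_gap_s: float = 1.0
    recommended_days: int = 104
    seed: int | None = None
    # simulator profile
    burst_rate_per_min: float = 60.0
    burst_duration_s: float = 2.0
    burst_amplitude: float = 60.0
    baseline_noise: float = 2.0
    asymmetry_rho: float = 1.0
    responsiveness_gain: float = 1.0

    def feedback_config(self) -> FeedbackConfig:
        return FeedbackConfig(
            threshold=ThresholdConfig(
                window_s=self.window_s, w_max=self.w_max, w_mean=self.w_mean, epsilon=self.epsilon
            ),
            ramp_up_s=self.ramp_up_s,
            ramp_down_s=self.ramp_down_s,
        )

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["controlling_limbs"] = list(self.controlling_limbs)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.as_dict(), sort_keys=True).encode()).hexdigest()[:12]

    @classmethod
    def merged(cls, file_values: dict | None = None, **overrides) -> "RunConfig":
        cfg = cls()
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for source in (file_values or {}, {k: v for k, v in overrides.items() if v is not None}):
            for key, raw in source.items():
                if key not in fields:
                    raise SchemaError(f"unknown config key {key!r}")
                setattr(cfg, key, _coerce(key, raw, getattr(cfg, key)))
        return cfg


def _coerce(key: str, raw, current):
    if key == "controlling_limbs":
        if isinstance(raw, str):
            raw = tuple(p.strip() for p in raw.split(",") if p.strip())
        limbs = tuple(raw)
        for limb in limbs:
            if limb not in LIMBS:
                raise SchemaError(f"unknown limb {limb!r} in controlling_limbs")
        return limbs
    if key == "seed":
        return None if raw in (None, "", "none") else int(raw)
    if isinstance(current, bool):
        return str(raw).lower() in ("1", "true", "yes")
    if isinstance(current, int):
        return int(raw)
    if isinstance(current, float):
        return float(raw)
    return raw


def parse_config_file(path: str) -> dict:
    """Parse flat ``key = value`` text into a raw string dict."""
    values: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise SchemaError(f"{path}: line {lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            values[key] = value
    return values
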