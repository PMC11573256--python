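"""Analysis configuration: windows, criteria, seeds, and the config hash."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["AnalysisConfig", "config_hash"]


@dataclass
class AnalysisConfig:
    """Every analysis-relevant parameter, serializable and hash-stamped.

    The defaults reproduce the standard analysis: 400/40/300-ms speech
    windows, the (0, 32] ms tone window, full-interval burst windows, the FRA
    extraction constants, uncorrected nonparametric group statistics, and the
    seed for the classifier's tie randomization.
    """

    speech_whole_window: tuple[float, float] = (0.0, 400.0)
    consonant_window: tuple[float, float] = (0.0, 40.0)
    vowel_window: tuple[float, float] = (40.0, 340.0)
    tone_window: tuple[float, float] = (0.0, 32.0)
    burst_response_window: float | None = None  # None -> full inter-burst interval

    classifier_bin_ms: float = 1.0
    classifier_tie_mode: str = "random"
    classifier_template_mode: str = "loo-own"

    rf_smooth_size: int = 3
    rf_criterion_fraction: float = 0.2
    rf_criterion_floor: float = 1.0
    rf_min_run: int = 2

    stats_family: str = "nonparametric"
    stats_alpha: float = 0.05
    stats_holm: bool = False

    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("speech_whole_window", "consonant_window", "vowel_window",
                    "tone_window"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())


def config_hash(config_dict: dict) -> str:
    """Stable 16-hex-digit hash of a configuration mapping."""
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
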