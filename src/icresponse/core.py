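"""Core data containers shared across the analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

from .stimuli import NoiseBurstTrain, SpeechToken, ToneGrid

GROUPS = ("saline", "vpa", "vpa_vns_speech", "vpa_vns_tone")


@dataclass
class TrialSpikes:
    """One repeat's spike timestamps, in ms relative to stimulus onset.

    The atomic recording unit: times are sorted ascending and non-negative.
    """

    spike_times: np.ndarray
    stimulus_id: str | None = None
    repeat_index: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times, dtype=float)
        if t.ndim != 1:
            raise ValueError("spike_times must be one-dimensional")
        if t.size and np.any(np.diff(t) < 0):
            raise ValueError("spike_times must be sorted ascending")
        if t.size and t[0] < 0:
            raise ValueError(f"spike_times must be >= 0, got {t[0]}")
        self.spike_times = t

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


@dataclass
class RecordingSite:
    """A multiunit recording site: group label, depth, and responses per stimulus.

    ``responses`` maps stimulus id -> list of :class:`TrialSpikes` (one per
    repeat).  ``params`` optionally carries the generator's ground-truth
    site parameters for synthetic sites.
    """

    site_id: str
    group: str
    animal_id: str
    depth_um: float
    responses: dict[str, list[TrialSpikes]] = field(default_factory=dict)
    params: Any = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")


@dataclass
class Cohort:
    """A set of recording sites plus the stimulus catalog they were recorded with."""

    sites: list[RecordingSite]
    effects: Mapping[str, Any]  # group label -> GroupEffectConfig
    seed: int
    grid: ToneGrid | None = None
    speech: list[SpeechToken] | None = None
    train: NoiseBurstTrain | None = None
    silence_repeats: int = 20
    silence_duration: float = 400.0

    def sites_by_group(self, group: str) -> list[RecordingSite]:
        return [s for s in self.sites if s.group == group]

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for s in self.sites:
            if s.group not in seen:
                seen.append(s.group)
        return seen

    def group_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.sites:
            counts[s.group] = counts.get(s.group, 0) + 1
        return counts
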