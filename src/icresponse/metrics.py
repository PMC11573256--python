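"""PSTHs and driven-firing-rate metrics over the standard analysis windows.

Windows are half-open ``[t0, t1)`` with 1-ms default binning, except the tone
response window which is the half-open interval ``(0, 32]`` following tone
onset (a spike exactly at onset is never stimulus-driven).  Driven rates are
spontaneous-subtracted and may be negative (suppression), reported as-is.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import TrialSpikes

__all__ = [
    "PSTH",
    "compute_psth",
    "driven_rate",
    "spontaneous_rate_estimate",
    "tone_response_strength",
    "window_counts",
]

_TOL = 1e-9


@dataclass
class PSTH:
    """Peristimulus time histogram pooled over repeats."""

    bin_edges: np.ndarray  # ms, length n_bins + 1
    counts: np.ndarray  # spikes per bin, pooled over trials
    n_trials: int

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def rate(self) -> np.ndarray:
        """Per-bin firing rate in Hz."""
        return self.counts / (self.n_trials * self.bin_width / 1000.0)

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0


def compute_psth(
    trials: Sequence[TrialSpikes], bin: float, window: tuple[float, float]
) -> PSTH:
    """Bin spikes from all trials into half-open bins ``[t, t + bin)``.

    The window width must divide evenly by ``bin``; spikes exactly at the
    window end fall outside the last half-open bin and are excluded.
    """
    if not trials:
        raise ValueError("compute_psth requires at least one trial")
    if bin <= 0:
        raise ValueError("bin width must be positive")
    w0, w1 = window
    if w1 <= w0:
        raise ValueError(f"empty window: {window}")
    n_bins = round((w1 - w0) / bin)
    if abs((w1 - w0) - n_bins * bin) > _TOL * max(1.0, abs(w1)):
        raise ValueError(
            f"window width {w1 - w0} ms is not divisible by bin {bin} ms"
        )
    edges = w0 + bin * np.arange(n_bins + 1)
    all_times = np.concatenate([t.spike_times for t in trials]) if trials else np.empty(0)
    in_win = all_times[(all_times >= w0) & (all_times < w1)]
    idx = np.floor((in_win - w0) / bin).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)  # guard against FP edge rounding
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    return PSTH(bin_edges=edges, counts=counts, n_trials=len(trials))


def window_counts(
    trials: Sequence[TrialSpikes],
    window: tuple[float, float],
    closed: str = "left",
) -> np.ndarray:
    """Spike count per trial in ``window``.

    ``closed="left"`` counts ``[t0, t1)`` (the PSTH convention);
    ``closed="right"`` counts ``(t0, t1]`` (the tone-window convention).
    """
    w0, w1 = window
    if closed == "left":
        return np.array(
            [np.count_nonzero((t.spike_times >= w0) & (t.spike_times < w1))
             for t in trials],
            dtype=float,
        )
    if closed == "right":
        return np.array(
            [np.count_nonzero((t.spike_times > w0) & (t.spike_times <= w1))
             for t in trials],
            dtype=float,
        )
    raise ValueError(f"closed must be 'left' or 'right', got {closed!r}")


def driven_rate(
    trials: Sequence[TrialSpikes],
    window: tuple[float, float],
    spontaneous: float,
) -> float:
    """Spontaneous-subtracted firing rate (Hz) over ``window``.

    (mean in-window spike count per trial) / (window width in s) minus the
    spontaneous rate.  Negative values indicate suppression below the
    spontaneous rate and are reported as-is.
    """
    if not trials:
        raise ValueError("driven_rate requires at least one trial")
    w0, w1 = window
    if w1 <= w0:
        raise ValueError(f"window width must be positive, got {window}")
    if spontaneous < 0:
        raise ValueError("spontaneous rate must be >= 0")
    counts = window_counts(trials, window, closed="left")
    return float(counts.mean() / ((w1 - w0) / 1000.0) - spontaneous)


def spontaneous_rate_estimate(
    pre_stimulus_trials: Sequence[TrialSpikes], window: tuple[float, float]
) -> float:
    """Mean firing rate (Hz) over stimulus-free sweeps."""
    w0, w1 = window
    if w1 <= w0:
        raise ValueError(f"window duration must be positive, got {window}")
    if not pre_stimulus_trials:
        raise ValueError("spontaneous_rate_estimate requires at least one trial")
    counts = window_counts(pre_stimulus_trials, window, closed="left")
    return float(counts.mean() / ((w1 - w0) / 1000.0))


def tone_response_strength(
    tone_trials: Sequence[Sequence[TrialSpikes]],
    window: tuple[float, float] = (0.0, 32.0),
) -> float:
    """Mean spikes per tone presentation within ``(0, 32]`` ms of tone onset.

    ``tone_trials`` holds one list of repeats per grid tone; the average runs
    over every presentation of every tone (all grid tones, not only those
    inside the receptive field — pass a restricted selection for the
    RF-limited variant).
    """
    if not tone_trials:
        raise ValueError("tone_response_strength requires grid responses")
    total = 0.0
    n = 0
    for trials in tone_trials:
        if not trials:
            raise ValueError("every grid tone needs at least one presentation")
        total += window_counts(trials, window, closed="right").sum()
        n += len(trials)
    return total / n
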