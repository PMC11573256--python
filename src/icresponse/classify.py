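"""Leave-one-out nearest-neighbor PSTH-template speech discrimination.

For a pair of speech sounds, each single-trial response is held out in turn
and compared, by Euclidean distance on binned spike-count vectors, to the
PSTH template of its own sound (mean of the remaining repeats) and to the
template of the other sound.  The trial is assigned to the nearer template;
accuracy is the percentage of held-out trials assigned to their own sound.

Consonant contrasts use forty 1-ms bins over the first 40 ms of the response;
vowel contrasts use a single 300-ms bin starting at the consonant offset, so
the distance reduces to an absolute spike-count difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .core import TrialSpikes
from .stimuli import CONSONANT_CONTRAST, VOWEL_CONTRAST

__all__ = [
    "BinningScheme",
    "ClassifierResult",
    "DiscriminationSummary",
    "consonant_scheme",
    "vowel_scheme",
    "bin_trials",
    "nn_classify_pair",
    "consonant_discrimination",
    "vowel_discrimination",
]

_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class BinningScheme:
    """Binning used to vectorize single-trial responses."""

    mode: str  # "consonant", "vowel", or "custom"
    window: tuple[float, float]
    bin: float  # ms

    def __post_init__(self) -> None:
        if self.mode == "consonant" and (self.window != (0.0, 40.0) or self.bin != 1.0):
            raise ValueError("consonant mode fixes window (0, 40) ms and 1-ms bins")
        if self.mode == "vowel" and (self.window != (40.0, 340.0) or self.bin != 300.0):
            raise ValueError("vowel mode fixes window (40, 340) ms and one 300-ms bin")
        w0, w1 = self.window
        n = round((w1 - w0) / self.bin)
        if n < 1 or abs((w1 - w0) - n * self.bin) > 1e-9:
            raise ValueError("window width must be a positive multiple of bin")

    @property
    def n_bins(self) -> int:
        return round((self.window[1] - self.window[0]) / self.bin)


def consonant_scheme() -> BinningScheme:
    """Forty 1-ms bins over the first 40 ms of the response."""
    return BinningScheme(mode="consonant", window=(0.0, 40.0), bin=1.0)


def vowel_scheme() -> BinningScheme:
    """A single 300-ms bin beginning at the consonant offset."""
    return BinningScheme(mode="vowel", window=(40.0, 340.0), bin=300.0)


@dataclass
class ClassifierResult:
    """Pairwise discrimination accuracy for one sound pair under one scheme."""

    pair: tuple[str, str]
    scheme: BinningScheme
    accuracy: float  # percent, in [0, 100]
    n_decisions: int
    n_ties: int = 0


@dataclass
class DiscriminationSummary:
    """Mean accuracy over a pair set, with the per-pair results."""

    mean_accuracy: float
    results: list[ClassifierResult]


def bin_trials(trials: Sequence[TrialSpikes], scheme: BinningScheme) -> np.ndarray:
    """(n_trials, n_bins) spike-count matrix under ``scheme`` (half-open bins)."""
    w0, w1 = scheme.window
    n = scheme.n_bins
    edges = w0 + scheme.bin * np.arange(n + 1)
    edges[-1] = w1
    out = np.empty((len(trials), n))
    for i, tr in enumerate(trials):
        t = tr.spike_times
        t = t[(t >= w0) & (t < w1)]
        idx = np.clip(np.floor((t - w0) / scheme.bin).astype(int), 0, n - 1)
        out[i] = np.bincount(idx, minlength=n)
    return out


def nn_classify_pair(
    trials_a: Sequence[TrialSpikes],
    trials_b: Sequence[TrialSpikes],
    scheme: BinningScheme,
    tie_seed: int = 0,
    labels: tuple[str, str] = ("a", "b"),
    tie_mode: str = "random",
    template_mode: str = "loo-own",
    expected_repeats: int | None = None,
) -> ClassifierResult:
    """Leave-one-out nearest-neighbor discrimination between two sounds.

    Each held-out trial is compared to its own sound's template built from
    the remaining repeats and to the other sound's template.  With the
    default ``template_mode="loo-own"`` the competing template uses all of
    the other sound's trials (the held-out trial is excluded wherever it
    appears, and only there); ``"loo-both"`` additionally drops the
    same-index repeat from the competing sound (requires equal trial counts).

    Exactly equal distances are ties: ``tie_mode="random"`` breaks them
    uniformly at random under ``tie_seed``; ``"expected"`` scores each tie
    as half a correct decision.
    """
    na, nb = len(trials_a), len(trials_b)
    if na < 2 or nb < 2:
        raise ValueError("nn_classify_pair needs >= 2 trials per sound")
    if expected_repeats is not None and (na != expected_repeats or nb != expected_repeats):
        warnings.warn(
            f"trial counts ({na}, {nb}) differ from the expected "
            f"{expected_repeats}; proceeding",
            stacklevel=2,
        )
    if template_mode not in ("loo-own", "loo-both"):
        raise ValueError(f"unknown template_mode {template_mode!r}")
    if template_mode == "loo-both" and na != nb:
        raise ValueError("template_mode='loo-both' requires equal trial counts")

    rng = np.random.default_rng(tie_seed)
    mats = (bin_trials(trials_a, scheme), bin_trials(trials_b, scheme))
    sums = (mats[0].sum(axis=0), mats[1].sum(axis=0))
    ns = (na, nb)

    correct = 0.0
    n_ties = 0
    for own in (0, 1):
        other = 1 - own
        x = mats[own]
        own_templates = (sums[own][None, :] - x) / (ns[own] - 1)
        if template_mode == "loo-own":
            other_template = sums[other][None, :] / ns[other]
            d_other = np.linalg.norm(x - other_template, axis=1)
        else:
            other_templates = (sums[other][None, :] - mats[other]) / (ns[other] - 1)
            d_other = np.linalg.norm(x - other_templates, axis=1)
        d_own = np.linalg.norm(x - own_templates, axis=1)
        scale = np.maximum(d_own, d_other)
        tie = np.abs(d_own - d_other) <= _TIE_RTOL * np.maximum(scale, 1.0)
        win = d_own < d_other
        correct += float(np.sum(win & ~tie))
        n_ties += int(tie.sum())
        if tie_mode == "expected":
            correct += 0.5 * float(tie.sum())
        elif tie_mode == "random":
            correct += float(np.sum(rng.random(int(tie.sum())) < 0.5))
        else:
            raise ValueError(f"unknown tie_mode {tie_mode!r}")

    n_decisions = na + nb
    return ClassifierResult(
        pair=labels,
        scheme=scheme,
        accuracy=100.0 * correct / n_decisions,
        n_decisions=n_decisions,
        n_ties=n_ties,
    )


def _pair_set(
    responses: Mapping[str, Sequence[TrialSpikes]],
    labels: Sequence[str],
    scheme: BinningScheme,
    tie_seed: int,
    tie_mode: str,
    expected_repeats: int | None,
) -> DiscriminationSummary:
    for lbl in labels:
        if lbl not in responses or not responses[lbl]:
            raise KeyError(f"missing responses for token {lbl!r}")
    results = []
    for i, (a, b) in enumerate(combinations(labels, 2)):
        results.append(
            nn_classify_pair(
                responses[a],
                responses[b],
                scheme,
                tie_seed=tie_seed + i,
                labels=(a, b),
                tie_mode=tie_mode,
                expected_repeats=expected_repeats,
            )
        )
    mean = float(np.mean([r.accuracy for r in results]))
    return DiscriminationSummary(mean_accuracy=mean, results=results)


def consonant_discrimination(
    responses: Mapping[str, Sequence[TrialSpikes]],
    tie_seed: int = 0,
    tie_mode: str = "random",
    expected_repeats: int | None = 20,
) -> DiscriminationSummary:
    """Mean accuracy over all 36 pairs of the nine "-ad" tokens (consonant scheme).

    ``responses`` maps token label -> trials; keys may be plain labels or the
    cohort's ``speech-<label>`` stimulus ids.
    """
    return _pair_set(
        _normalize_keys(responses), CONSONANT_CONTRAST, consonant_scheme(),
        tie_seed, tie_mode, expected_repeats,
    )


def vowel_discrimination(
    responses: Mapping[str, Sequence[TrialSpikes]],
    tie_seed: int = 0,
    tie_mode: str = "random",
    expected_repeats: int | None = 20,
) -> DiscriminationSummary:
    """Mean accuracy over the 3 vowel-contrast pairs dad/deed/dood (vowel scheme)."""
    return _pair_set(
        _normalize_keys(responses), VOWEL_CONTRAST, vowel_scheme(),
        tie_seed, tie_mode, expected_repeats,
    )


def _normalize_keys(
    responses: Mapping[str, Sequence[TrialSpikes]]
) -> dict[str, Sequence[TrialSpikes]]:
    out = {}
    for key, val in responses.items():
        label = key[len("speech-"):] if key.startswith("speech-") else key
        out[label] = val
    return out
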