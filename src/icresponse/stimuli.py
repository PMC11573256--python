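"""Stimulus sets: the tone grid, VNS-paired tones, noise-burst trains, and speech tokens.

All times are milliseconds relative to stimulus onset, intensities are dB SPL,
and frequencies are Hz.  The stimulus objects carry no audio; they are the
design-level description the recordings and the synthetic generator share
(frequencies, levels, timing, and the analysis windows of each speech token).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

__all__ = [
    "ToneStimulus",
    "ToneGrid",
    "NoiseBurstTrain",
    "SpeechToken",
    "build_tone_grid",
    "build_paired_tone_set",
    "build_noise_train",
    "speech_catalog",
    "consonant_tokens",
    "vowel_tokens",
    "catalog_to_json",
    "tone_id",
    "speech_id",
    "BURST_ID",
    "SILENCE_ID",
]

#: Labels of the eleven speech tokens, in catalog order.
SPEECH_LABELS = (
    "chad", "dad", "deed", "dood", "fad", "gad",
    "had", "jad", "sad", "shad", "tad",
)

#: The nine tokens sharing the "-ad" vowel, differing only in initial consonant.
CONSONANT_CONTRAST = (
    "chad", "dad", "fad", "gad", "had", "jad", "sad", "shad", "tad",
)

#: The three tokens sharing the initial "d", differing only in vowel.
VOWEL_CONTRAST = ("dad", "deed", "dood")

BURST_ID = "burst-train"
SILENCE_ID = "silence"

_DIVISIBILITY_TOL = 1e-6  # octaves


def tone_id(index: int) -> str:
    """Stable stimulus id for the ``index``-th tone of a grid (frequency-major order)."""
    return f"tone-{index:04d}"


def speech_id(label: str) -> str:
    return f"speech-{label}"


@dataclass(frozen=True)
class ToneStimulus:
    """A pure-tone pip.

    Parameters
    ----------
    frequency : float
        Carrier frequency, Hz.
    intensity : float
        Presentation level, dB SPL.
    duration : float
        Pip duration in ms (default 25).
    ramp : float
        Cosine on/off ramp in ms (default 5); ``2 * ramp`` may not exceed duration.
    """

    frequency: float
    intensity: float
    duration: float = 25.0
    ramp: float = 5.0

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError(f"frequency must be positive, got {self.frequency}")
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if self.ramp < 0 or 2 * self.ramp > self.duration:
            raise ValueError(
                f"ramp must satisfy 0 <= 2*ramp <= duration, got ramp={self.ramp}"
            )


@dataclass(frozen=True)
class ToneGrid:
    """A frequency x intensity tuning grid, frequency-major stimulus order."""

    frequencies: tuple[float, ...]
    intensities: tuple[float, ...]
    stimuli: tuple[ToneStimulus, ...]
    octave_step: float

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.frequencies), len(self.intensities))

    @property
    def n_stimuli(self) -> int:
        return len(self.stimuli)

    def stimulus_index(self, freq_index: int, int_index: int) -> int:
        """Flat index of the stimulus at grid position (freq_index, int_index)."""
        return freq_index * len(self.intensities) + int_index

    @property
    def db_step(self) -> float:
        if len(self.intensities) < 2:
            return 0.0
        return self.intensities[1] - self.intensities[0]


@dataclass(frozen=True)
class NoiseBurstTrain:
    """A periodic train of white-noise bursts."""

    n_bursts: int
    rate: float  # Hz
    burst_duration: float  # ms
    onsets: tuple[float, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if self.n_bursts < 1:
            raise ValueError(f"n_bursts must be >= 1, got {self.n_bursts}")
        if self.burst_duration <= 0:
            raise ValueError("burst_duration must be positive")
        period = 1000.0 / self.rate
        object.__setattr__(
            self, "onsets", tuple(k * period for k in range(self.n_bursts))
        )

    @property
    def period(self) -> float:
        """Inter-burst interval, ms."""
        return 1000.0 / self.rate


@dataclass(frozen=True)
class SpeechToken:
    """A speech token described by its analysis windows.

    The token is an analysis object, not a waveform: the consonant window is
    the first 40 ms of the response, the vowel window the following 300 ms,
    and the whole-token window the first 400 ms.
    """

    label: str
    consonant_window: tuple[float, float] = (0.0, 40.0)
    vowel_window: tuple[float, float] = (40.0, 340.0)
    whole_window: tuple[float, float] = (0.0, 400.0)
    n_repeats: int = 20

    @property
    def vowel(self) -> str:
        if self.label == "deed":
            return "ee"
        if self.label == "dood":
            return "oo"
        return "a"


def build_tone_grid(
    f_lo: float,
    f_hi: float,
    octave_step: float,
    db_lo: float,
    db_hi: float,
    db_step: float,
    duration: float = 25.0,
    ramp: float = 5.0,
) -> ToneGrid:
    """Construct a log-spaced frequency x linear intensity tuning grid.

    Frequencies run ``f_lo * 2**(k * octave_step)`` up to and including
    ``f_hi`` (the span must divide evenly by ``octave_step``); intensities run
    ``db_lo`` to ``db_hi`` inclusive in steps of ``db_step``.  The default
    recording design, ``build_tone_grid(1000, 32000, 0.0625, 0, 75, 5)``,
    yields 81 frequencies x 16 intensities = 1,296 tones.
    """
    if f_lo <= 0 or f_hi <= f_lo:
        raise ValueError(f"need 0 < f_lo < f_hi, got ({f_lo}, {f_hi})")
    if octave_step <= 0:
        raise ValueError("octave_step must be positive")
    if db_step <= 0:
        raise ValueError("db_step must be positive")
    if db_lo > db_hi:
        raise ValueError(f"empty intensity range: ({db_lo}, {db_hi})")

    span = math.log2(f_hi / f_lo)
    n_steps = round(span / octave_step)
    residual = abs(span - n_steps * octave_step)
    if residual > _DIVISIBILITY_TOL:
        raise ValueError(
            f"frequency span {span:.6f} octaves is not divisible by "
            f"octave_step={octave_step} (residual {residual:.3g} octaves)"
        )

    frequencies = tuple(f_lo * 2.0 ** (k * octave_step) for k in range(n_steps + 1))
    n_db = int(round((db_hi - db_lo) / db_step)) + 1
    intensities = tuple(db_lo + k * db_step for k in range(n_db))
    stimuli = tuple(
        ToneStimulus(frequency=f, intensity=i, duration=duration, ramp=ramp)
        for f in frequencies
        for i in intensities
    )
    return ToneGrid(
        frequencies=frequencies,
        intensities=intensities,
        stimuli=stimuli,
        octave_step=octave_step,
    )


#: (frequency kHz, intensity dB SPL) pairs of the VNS-paired tone set; the
#: intensities follow the contour of the rat audiogram.
_PAIRED_TONES = (
    (1.3, 55.0), (2.2, 50.0), (3.7, 40.0), (6.3, 35.0),
    (10.6, 35.0), (17.8, 45.0), (29.9, 55.0),
)


def build_paired_tone_set() -> list[ToneStimulus]:
    """The seven tones used for VNS-tone pairing, spanning the rat hearing range."""
    return [
        ToneStimulus(frequency=f_khz * 1000.0, intensity=db)
        for f_khz, db in _PAIRED_TONES
    ]


def build_noise_train(
    rate: float, n_bursts: int, burst_duration: float
) -> NoiseBurstTrain:
    """A noise-burst train at ``rate`` Hz; onsets at 0, 1000/rate, ... ms."""
    return NoiseBurstTrain(n_bursts=n_bursts, rate=rate, burst_duration=burst_duration)


def speech_catalog() -> list[SpeechToken]:
    """The eleven speech tokens, 20 repeats each, with the standard windows."""
    return [SpeechToken(label=label) for label in SPEECH_LABELS]


def consonant_tokens(catalog: list[SpeechToken] | None = None) -> list[SpeechToken]:
    """The nine "-ad" tokens used for consonant-contrast discrimination."""
    catalog = catalog if catalog is not None else speech_catalog()
    by_label = {t.label: t for t in catalog}
    missing = [lbl for lbl in CONSONANT_CONTRAST if lbl not in by_label]
    if missing:
        raise KeyError(f"catalog is missing consonant-contrast tokens: {missing}")
    return [by_label[lbl] for lbl in CONSONANT_CONTRAST]


def vowel_tokens(catalog: list[SpeechToken] | None = None) -> list[SpeechToken]:
    """The three vowel-contrast tokens: dad, deed, dood."""
    catalog = catalog if catalog is not None else speech_catalog()
    by_label = {t.label: t for t in catalog}
    missing = [lbl for lbl in VOWEL_CONTRAST if lbl not in by_label]
    if missing:
        raise KeyError(f"catalog is missing vowel-contrast tokens: {missing}")
    return [by_label[lbl] for lbl in VOWEL_CONTRAST]


def catalog_to_json(
    grid: ToneGrid | None = None,
    speech: list[SpeechToken] | None = None,
    train: NoiseBurstTrain | None = None,
    paired_tones: list[ToneStimulus] | None = None,
) -> str:
    """Serialize stimulus sets to a JSON document with stable key order."""
    doc: dict = {}
    if grid is not None:
        doc["tone_grid"] = {
            "frequencies_hz": list(grid.frequencies),
            "intensities_db": list(grid.intensities),
            "octave_step": grid.octave_step,
            "n_stimuli": grid.n_stimuli,
            "duration_ms": grid.stimuli[0].duration,
            "ramp_ms": grid.stimuli[0].ramp,
        }
    if speech is not None:
        doc["speech_tokens"] = [
            {
                "label": t.label,
                "consonant_window_ms": list(t.consonant_window),
                "vowel_window_ms": list(t.vowel_window),
                "whole_window_ms": list(t.whole_window),
                "n_repeats": t.n_repeats,
            }
            for t in speech
        ]
    if train is not None:
        doc["noise_train"] = {
            "n_bursts": train.n_bursts,
            "rate_hz": train.rate,
            "burst_duration_ms": train.burst_duration,
            "onsets_ms": list(train.onsets),
        }
    if paired_tones is not None:
        doc["paired_tones"] = [
            {"frequency_hz": t.frequency, "intensity_db": t.intensity}
            for t in paired_tones
        ]
    return json.dumps(doc, indent=2, sort_keys=True)
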