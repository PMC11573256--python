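"""Synthetic multiunit cohort generator.

Generates inhomogeneous-Poisson spike trains for the four experimental groups
(saline, VPA, VPA + VNS-speech, VPA + VNS-tone) with the statistical structure
the downstream analyses assume:

* spontaneous Poisson background at a site-specific rate;
* V-shaped tone tuning over the frequency x intensity grid (one presentation
  per grid tone), with an onset transient whose latencies the receptive-field
  extractor can recover;
* speech responses built from an onset (consonant) transient plus a sustained
  (vowel) plateau, with group-dependent gains;
* phase-locked transients to each burst of the 10-Hz noise-burst train, with
  group-dependent gain and latency shifts;
* a silent "stimulus" used to estimate each site's spontaneous rate.

Group contrasts enter only through :class:`GroupEffectConfig`; site parameter
distributions are otherwise identical across groups.  The packaged defaults
(:func:`default_group_effects`) encode the reported group contrasts: the VPA
group's speech gain is reduced relative to saline, VNS-tone pairing raises the
whole-window speech response 44% above the VPA group, and VNS-speech pairing
lowers it 5% while depressing the consonant and enhancing the vowel component;
VNS-tone pairing also strengthens and speeds burst responses, while tone
responses are left equal across groups.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .core import GROUPS, Cohort, RecordingSite, TrialSpikes
from .kernels import bump, bump_integral
from .stimuli import (
    BURST_ID,
    SILENCE_ID,
    NoiseBurstTrain,
    SpeechToken,
    ToneGrid,
    ToneStimulus,
    speech_id,
    tone_id,
)

__all__ = [
    "SiteParams",
    "GroupEffectConfig",
    "RateProfile",
    "default_group_effects",
    "rate_profile",
    "simulate_trials",
    "generate_cohort",
    "expected_tone_count",
    "tuning_amplitude",
]

# ---------------------------------------------------------------------------
# Response-scale constants (fractions of a site's peak driven rate).
#
# peak_driven_rate is the instantaneous PSTH peak of the tone onset response
# at the characteristic frequency, well above threshold.  Speech and burst
# responses are scaled relative to it: broadband onsets are weaker than the
# best-frequency tone onset, and the sustained vowel response is a low-rate
# plateau.  TONE_AMP_FLOOR sets the onset amplitude at threshold relative to
# the amplitude 40 dB above it (rate-level growth is shallow in IC multiunits).
TONE_AMP_FLOOR = 0.85
CONSONANT_PEAK_FACTOR = 0.30
VOWEL_PLATEAU_FACTOR = 0.009
BURST_PEAK_FACTOR = 0.35

#: Duration (ms) of the simulated sweep for each stimulus class.
TONE_SWEEP_MS = 50.0
SPEECH_SWEEP_MS = 400.0
SILENCE_SWEEP_MS = 400.0
#: Burst sweeps run to the last burst onset plus one full period.

# Per-token response profile: (consonant amplitude factor, consonant latency
# offset ms, vowel plateau factor).  Onset amplitudes are stronger for stops
# and affricates than fricatives/aspirates, and fricative onsets are delayed;
# the three "d"-initial tokens share one consonant profile so the vowel
# contrast isolates the vowel window.  Consonant factors average 1.0 over the
# nine "-ad" tokens and vowel factors average 1.0 over the full catalog.
TOKEN_PROFILES: dict[str, tuple[float, float, float]] = {
    "chad": (1.30, 3.0, 1.0),
    "dad": (1.00, 0.0, 1.0),
    "deed": (1.00, 0.0, 0.5),
    "dood": (1.00, 0.0, 1.5),
    "fad": (0.70, 5.0, 1.0),
    "gad": (1.10, 1.0, 1.0),
    "had": (0.60, 10.0, 1.0),
    "jad": (1.20, 2.0, 1.0),
    "sad": (0.90, 6.0, 1.0),
    "shad": (0.80, 8.0, 1.0),
    "tad": (1.40, 2.0, 1.0),
}

# Reference latencies used only to fix the consonant/vowel energy split of the
# default calibration (the realized split uses each site's own latencies, whose
# means match these).
_REF_LATENCIES = (8.2, 13.4, 27.1)


def speech_consonant_share() -> float:
    """Fraction of expected whole-window driven spikes carried by the consonant.

    Computed from the default response-scale constants; used to balance the
    consonant/vowel gains of the VNS-speech group so its whole-window contrast
    is exactly -5% while the consonant decreases and the vowel increases.
    """
    n_cons = CONSONANT_PEAK_FACTOR * bump_integral(*_REF_LATENCIES) / 1000.0
    n_vowel = VOWEL_PLATEAU_FACTOR * 0.300
    return n_cons / (n_cons + n_vowel)


@dataclass(frozen=True)
class SiteParams:
    """Ground-truth response parameters of one synthetic site."""

    cf: float  # Hz
    threshold: float  # dB SPL
    bw10: float  # octaves
    bw40: float  # octaves
    onset_latency: float  # ms
    peak_latency: float  # ms
    end_of_peak: float  # ms
    spontaneous_rate: float  # Hz
    depth: float  # um
    peak_driven_rate: float  # Hz

    def __post_init__(self) -> None:
        if not self.bw40 >= self.bw10 > 0:
            raise ValueError(f"need bw40 >= bw10 > 0, got ({self.bw10}, {self.bw40})")
        if not self.onset_latency < self.peak_latency < self.end_of_peak:
            raise ValueError(
                "need onset_latency < peak_latency < end_of_peak, got "
                f"({self.onset_latency}, {self.peak_latency}, {self.end_of_peak})"
            )
        if self.spontaneous_rate < 0:
            raise ValueError("spontaneous_rate must be >= 0")
        if self.peak_driven_rate < 0:
            raise ValueError("peak_driven_rate must be >= 0")


@dataclass(frozen=True)
class GroupEffectConfig:
    """Per-group response-gain and latency parameters of the generator."""

    group: str
    speech_gain: float = 1.0
    consonant_gain: float = 1.0
    vowel_gain: float = 1.0
    tone_gain: float = 1.0
    burst_gain: float = 1.0
    burst_onset_shift: float = 0.0  # ms
    burst_peak_shift: float = 0.0  # ms
    mean_threshold: float = 17.35  # dB SPL
    n_sites: int = 150
    n_animals: int = 10

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        for name in ("speech_gain", "consonant_gain", "vowel_gain", "tone_gain",
                     "burst_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")


def default_group_effects(
    n_sites: Mapping[str, int] | int | None = None,
) -> dict[str, GroupEffectConfig]:
    """The packaged default group-effect configuration.

    Encodes the reported group contrasts: VPA speech gain 0.70 x saline;
    VNS-tone speech gain 1.44 x VPA (and burst gain 1.30 with -1 ms latency
    shifts); VNS-speech speech gain 0.95 x VPA with the consonant gain at 0.8
    and the vowel gain raised so the whole-window contrast stays at -5%.
    Tone gains are equal across groups.  Mean thresholds are the per-group
    calibration anchors (17.35, 17.35, 17.78, 12.35 dB); default site counts
    match the recorded cohort (453, 374, 183, 146).

    Parameters
    ----------
    n_sites : mapping, int, or None
        Override the per-group site counts (an int applies to every group).
    """
    w = speech_consonant_share()
    cons = 0.8
    vowel = (1.0 - w * cons) / (1.0 - w)
    vpa_speech = 0.70
    cfg = {
        "saline": GroupEffectConfig(
            group="saline", mean_threshold=17.35, n_sites=453, n_animals=19
        ),
        "vpa": GroupEffectConfig(
            group="vpa", speech_gain=vpa_speech, mean_threshold=17.35,
            n_sites=374, n_animals=18,
        ),
        "vpa_vns_speech": GroupEffectConfig(
            group="vpa_vns_speech",
            speech_gain=0.95 * vpa_speech,
            consonant_gain=cons,
            vowel_gain=vowel,
            burst_gain=0.85,
            mean_threshold=17.78,
            n_sites=183,
            n_animals=8,
        ),
        "vpa_vns_tone": GroupEffectConfig(
            group="vpa_vns_tone",
            speech_gain=1.44 * vpa_speech,
            burst_gain=1.30,
            burst_onset_shift=-1.0,
            burst_peak_shift=-1.0,
            mean_threshold=12.35,
            n_sites=146,
            n_animals=7,
        ),
    }
    if n_sites is not None:
        if isinstance(n_sites, int):
            cfg = {g: replace(c, n_sites=n_sites) for g, c in cfg.items()}
        else:
            cfg = {
                g: replace(c, n_sites=n_sites.get(g, c.n_sites))
                for g, c in cfg.items()
            }
    return cfg


# ---------------------------------------------------------------------------
# Rate profiles


class RateProfile:
    """A piecewise firing-rate function: spontaneous + transients + plateaus.

    ``transients`` are (amplitude Hz, onset, peak, end) bumps; ``plateaus``
    are (amplitude Hz, t0, t1) boxes.  The structured form lets the simulator
    draw the homogeneous components exactly and thin only over each
    transient's support.
    """

    def __init__(
        self,
        spontaneous: float,
        transients: Sequence[tuple[float, float, float, float]] = (),
        plateaus: Sequence[tuple[float, float, float]] = (),
    ) -> None:
        if spontaneous < 0:
            raise ValueError("spontaneous rate must be >= 0")
        self.spontaneous = float(spontaneous)
        self.transients = [tuple(map(float, tr)) for tr in transients]
        self.plateaus = [tuple(map(float, pl)) for pl in plateaus]
        for amp, *_ in self.transients + self.plateaus:
            if amp < 0:
                raise ValueError("component amplitudes must be >= 0")

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, self.spontaneous)
        for amp, o, p, e in self.transients:
            out += amp * bump(t, o, p, e)
        for amp, t0, t1 in self.plateaus:
            out += amp * ((t >= t0) & (t < t1))
        return out

    @property
    def max_rate(self) -> float:
        """An exact upper bound on the rate (tight when components don't overlap)."""
        intervals = [(o, e, amp) for amp, o, p, e in self.transients]
        intervals += [(t0, t1, amp) for amp, t0, t1 in self.plateaus]
        if not intervals:
            return self.spontaneous
        # Sum amplitudes of mutually overlapping components: a valid bound,
        # tight whenever supports are disjoint (the usual case here).
        best = 0.0
        for o, e, amp in intervals:
            tot = amp
            for o2, e2, amp2 in intervals:
                if (o2, e2, amp2) != (o, e, amp) and o2 < e and e2 > o:
                    tot += amp2
            best = max(best, tot)
        return self.spontaneous + best


def tuning_amplitude(
    frequency: float, intensity: float, site: SiteParams
) -> float:
    """Relative driven amplitude of a tone at (frequency, intensity), in [0, 1].

    Zero below threshold; above it, the responsive frequency band is centred
    on the CF with an octave extent that widens linearly with level through
    (bw10 at threshold+10 dB, bw40 at threshold+40 dB).  Within the band the
    amplitude grows from ``TONE_AMP_FLOOR`` at threshold to 1 at
    threshold+40 dB and saturates above.
    """
    rel = intensity - site.threshold
    if rel < 0:
        return 0.0
    extent = site.bw10 + (site.bw40 - site.bw10) * (rel - 10.0) / 30.0
    if extent <= 0:
        return 0.0
    if abs(np.log2(frequency / site.cf)) > extent / 2.0:
        return 0.0
    return TONE_AMP_FLOOR + (1.0 - TONE_AMP_FLOOR) * min(1.0, rel / 40.0)


def rate_profile(
    stimulus: ToneStimulus | SpeechToken | NoiseBurstTrain | None,
    site: SiteParams,
    effects: GroupEffectConfig,
) -> RateProfile:
    """The firing-rate function of ``site`` responding to ``stimulus``.

    ``None`` denotes silence (spontaneous activity only).  Tones drive an
    onset transient scaled by the tuning surface; speech tokens drive a
    consonant transient plus a vowel plateau; noise-burst trains drive one
    transient per burst onset with the group's gain and latency shifts.
    """
    spont = site.spontaneous_rate
    o, p, e = site.onset_latency, site.peak_latency, site.end_of_peak

    if stimulus is None:
        return RateProfile(spont)

    if isinstance(stimulus, ToneStimulus):
        amp = (
            effects.tone_gain
            * site.peak_driven_rate
            * tuning_amplitude(stimulus.frequency, stimulus.intensity, site)
        )
        transients = [(amp, o, p, e)] if amp > 0 else []
        return RateProfile(spont, transients=transients)

    if isinstance(stimulus, SpeechToken):
        cons_amp, cons_delay, vowel_factor = TOKEN_PROFILES[stimulus.label]
        a_cons = (
            effects.speech_gain
            * effects.consonant_gain
            * cons_amp
            * CONSONANT_PEAK_FACTOR
            * site.peak_driven_rate
        )
        a_vowel = (
            effects.speech_gain
            * effects.vowel_gain
            * vowel_factor
            * VOWEL_PLATEAU_FACTOR
            * site.peak_driven_rate
        )
        transients = (
            [(a_cons, o + cons_delay, p + cons_delay, e + cons_delay)]
            if a_cons > 0
            else []
        )
        v0, v1 = stimulus.vowel_window
        plateaus = [(a_vowel, v0, v1)] if a_vowel > 0 else []
        return RateProfile(spont, transients=transients, plateaus=plateaus)

    if isinstance(stimulus, NoiseBurstTrain):
        amp = effects.burst_gain * BURST_PEAK_FACTOR * site.peak_driven_rate
        transients = []
        if amp > 0:
            for onset in stimulus.onsets:
                transients.append(
                    (
                        amp,
                        onset + o + effects.burst_onset_shift,
                        onset + p + effects.burst_peak_shift,
                        onset + e,
                    )
                )
        return RateProfile(spont, transients=transients)

    raise TypeError(f"unrecognized stimulus type: {type(stimulus).__name__}")


def expected_tone_count(
    stimulus: ToneStimulus,
    site: SiteParams,
    effects: GroupEffectConfig,
    window: tuple[float, float] = (0.0, 32.0),
) -> float:
    """Expected spike count of the tone response in ``window`` (driven + spontaneous)."""
    amp = (
        effects.tone_gain
        * site.peak_driven_rate
        * tuning_amplitude(stimulus.frequency, stimulus.intensity, site)
    )
    w0, w1 = window
    o, p, e = site.onset_latency, site.peak_latency, site.end_of_peak
    lo, hi = max(o, w0), min(e, w1)
    driven = 0.0
    if amp > 0 and hi > lo:
        t = np.linspace(lo, hi, 1001)
        driven = amp * float(np.trapezoid(bump(t, o, p, e), t)) / 1000.0
    return driven + site.spontaneous_rate * (w1 - w0) / 1000.0


# ---------------------------------------------------------------------------
# Simulation


def _as_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def _homogeneous(
    rate: float, t0: float, t1: float, n_repeats: int, rng: np.random.Generator
) -> list[np.ndarray]:
    dur_s = (t1 - t0) / 1000.0
    counts = rng.poisson(rate * dur_s, size=n_repeats)
    return [rng.uniform(t0, t1, size=c) for c in counts]


def _thinned_bump(
    amp: float,
    onset: float,
    peak: float,
    end: float,
    n_repeats: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    dur_s = (end - onset) / 1000.0
    counts = rng.poisson(amp * dur_s, size=n_repeats)
    out = []
    for c in counts:
        t = rng.uniform(onset, end, size=c)
        keep = rng.random(c) < bump(t, onset, peak, end)
        out.append(t[keep])
    return out


def simulate_trials(
    rate_fn: Callable[[np.ndarray], np.ndarray] | RateProfile,
    duration: float,
    n_repeats: int,
    rng_seed=0,
    stimulus_id: str | None = None,
) -> list[TrialSpikes]:
    """Independent inhomogeneous-Poisson realizations of ``rate_fn`` on (0, duration].

    A :class:`RateProfile` is simulated piecewise (exact draws for the
    homogeneous components, thinning over each transient's support, using the
    profile's exact rate bound).  A generic callable is simulated by thinning
    against 1.05x its maximum on a 4096-point grid; the callable must be
    vectorized and non-negative.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = _as_rng(rng_seed)

    if isinstance(rate_fn, RateProfile):
        parts: list[list[np.ndarray]] = [
            _homogeneous(rate_fn.spontaneous, 0.0, duration, n_repeats, rng)
        ]
        for amp, o, p, e in rate_fn.transients:
            lo, hi = max(o, 0.0), min(e, duration)
            if hi > lo and amp > 0:
                if (o, e) != (lo, hi):
                    # truncated support: thin against the full bump
                    sub = []
                    counts = rng.poisson(amp * (hi - lo) / 1000.0, size=n_repeats)
                    for c in counts:
                        t = rng.uniform(lo, hi, size=c)
                        keep = rng.random(c) < bump(t, o, p, e)
                        sub.append(t[keep])
                    parts.append(sub)
                else:
                    parts.append(_thinned_bump(amp, o, p, e, n_repeats, rng))
        for amp, t0, t1 in rate_fn.plateaus:
            lo, hi = max(t0, 0.0), min(t1, duration)
            if hi > lo and amp > 0:
                parts.append(_homogeneous(amp, lo, hi, n_repeats, rng))
        trials = []
        for i in range(n_repeats):
            times = np.sort(np.concatenate([part[i] for part in parts]))
            trials.append(
                TrialSpikes(times, stimulus_id=stimulus_id, repeat_index=i)
            )
        return trials

    # Generic callable: global thinning.
    grid = np.linspace(0.0, duration, 4096)
    vals = np.asarray(rate_fn(grid), dtype=float)
    if np.any(vals < 0):
        raise ValueError("rate function is negative on [0, duration]")
    lam = 1.05 * float(vals.max()) + 1e-12
    counts = rng.poisson(lam * duration / 1000.0, size=n_repeats)
    trials = []
    for i, c in enumerate(counts):
        t = rng.uniform(0.0, duration, size=c)
        r = np.asarray(rate_fn(t), dtype=float)
        if np.any(r < 0):
            raise ValueError("rate function is negative on [0, duration]")
        keep = rng.random(c) * lam < r
        trials.append(
            TrialSpikes(np.sort(t[keep]), stimulus_id=stimulus_id, repeat_index=i)
        )
    return trials


def _simulate_tone_grid(
    site: SiteParams,
    effects: GroupEffectConfig,
    grid: ToneGrid,
    rng: np.random.Generator,
    duration: float = TONE_SWEEP_MS,
) -> dict[str, list[TrialSpikes]]:
    """One presentation of every grid tone, drawn in a single vectorized pass.

    All tone responses at a site share the same transient timing and differ
    only in amplitude, so the spontaneous background is drawn exactly for all
    tones at once and the driven transients are thinned jointly.
    """
    nf, ni = grid.shape
    amps = np.empty(nf * ni)
    for fi, f in enumerate(grid.frequencies):
        for ii, inten in enumerate(grid.intensities):
            amps[grid.stimulus_index(fi, ii)] = (
                effects.tone_gain
                * site.peak_driven_rate
                * tuning_amplitude(f, inten, site)
            )
    n_stim = amps.size
    o, p, e = site.onset_latency, site.peak_latency, site.end_of_peak

    spont_counts = rng.poisson(site.spontaneous_rate * duration / 1000.0, size=n_stim)
    hi = min(e, duration)
    driven_counts = (
        rng.poisson(amps * (hi - o) / 1000.0, size=n_stim)
        if hi > o
        else np.zeros(n_stim, dtype=int)
    )

    total_driven = int(driven_counts.sum())
    t_driven = rng.uniform(o, hi, size=total_driven)
    keep = rng.random(total_driven) < bump(t_driven, o, p, e)
    stim_of_driven = np.repeat(np.arange(n_stim), driven_counts)

    responses: dict[str, list[TrialSpikes]] = {}
    # split accepted driven spikes per stimulus
    driven_lists: list[np.ndarray] = [np.empty(0)] * n_stim
    if total_driven:
        kept_stim = stim_of_driven[keep]
        kept_t = t_driven[keep]
        order = np.argsort(kept_stim, kind="stable")
        kept_stim = kept_stim[order]
        kept_t = kept_t[order]
        bounds = np.searchsorted(kept_stim, np.arange(n_stim + 1))
        driven_lists = [kept_t[bounds[k]: bounds[k + 1]] for k in range(n_stim)]

    for k in range(n_stim):
        spont_t = rng.uniform(0.0, duration, size=spont_counts[k])
        times = np.sort(np.concatenate([spont_t, driven_lists[k]]))
        responses[tone_id(k)] = [
            TrialSpikes(times, stimulus_id=tone_id(k), repeat_index=0)
        ]
    return responses


def _draw_site_params(
    effects: GroupEffectConfig, rng: np.random.Generator
) -> SiteParams:
    """Draw one site's ground-truth parameters.

    CF is log-uniform on 1-32 kHz and mapped monotonically to recording depth
    (800 um per octave from 1,000 um, with 150-um jitter) to create tonotopy.
    Thresholds are drawn about the group mean (SD 8 dB) and snapped to the
    5-dB grid lattice, since a threshold is only ever observed at a grid
    level.  Latency and bandwidth distributions are centred on the saline
    calibration anchors and are identical across groups.
    """
    octaves = rng.uniform(0.0, 5.0)
    cf = 1000.0 * 2.0 ** octaves
    depth = float(np.clip(1000.0 + 800.0 * octaves + rng.normal(0.0, 150.0),
                          1000.0, 5000.0))
    threshold = float(
        np.clip(5.0 * np.round(rng.normal(effects.mean_threshold, 8.0) / 5.0),
                0.0, 70.0)
    )
    bw10 = float(np.clip(rng.normal(1.33, 0.25), 0.4, 3.0))
    bw40 = bw10 + float(np.clip(rng.normal(0.40, 0.15), 0.1, 1.5))
    onset = float(np.clip(rng.normal(8.2, 0.7), 5.0, 12.0))
    peak = onset + float(np.clip(rng.normal(5.2, 0.7), 2.0, 9.0))
    end = peak + float(np.clip(rng.normal(13.7, 1.5), 6.0, 25.0))
    # lognormal with mean 30 Hz (CV 0.4) and mean 1400 Hz (CV 0.25)
    sig_s = np.sqrt(np.log(1.0 + 0.4 ** 2))
    spont = float(np.clip(rng.lognormal(np.log(30.0) - sig_s ** 2 / 2, sig_s),
                          1.0, 120.0))
    sig_p = np.sqrt(np.log(1.0 + 0.25 ** 2))
    peak_rate = float(
        np.clip(rng.lognormal(np.log(1400.0) - sig_p ** 2 / 2, sig_p), 300.0, 4000.0)
    )
    return SiteParams(
        cf=cf,
        threshold=threshold,
        bw10=bw10,
        bw40=bw40,
        onset_latency=onset,
        peak_latency=peak,
        end_of_peak=end,
        spontaneous_rate=spont,
        depth=depth,
        peak_driven_rate=peak_rate,
    )


def generate_cohort(
    effects: Mapping[str, GroupEffectConfig],
    grid: ToneGrid | None = None,
    speech: Sequence[SpeechToken] | None = None,
    train: NoiseBurstTrain | None = None,
    seed: int = 0,
    groups: Sequence[str] | None = None,
    silence_repeats: int = 20,
    silence_duration: float = SILENCE_SWEEP_MS,
) -> Cohort:
    """Generate a synthetic cohort for the configured groups.

    Every group in :data:`icresponse.core.GROUPS` must be configured in
    ``effects``; ``groups`` optionally restricts which of them are actually
    generated (the configuration stays complete either way).  Each site holds
    one simulated presentation of every grid tone, 20 repeats of every speech
    token, 20 repeats of the noise-burst train, and ``silence_repeats``
    spontaneous-only sweeps used for spontaneous-rate estimation.  One RNG
    stream per (seed, group index, site index) makes cohorts bit-reproducible.
    """
    missing = [g for g in GROUPS if g not in effects]
    if missing:
        raise ValueError(f"missing GroupEffectConfig for groups: {missing}")
    gen_groups = list(GROUPS) if groups is None else list(groups)
    for g in gen_groups:
        if g not in effects:
            raise ValueError(f"missing GroupEffectConfig for group {g!r}")

    sites: list[RecordingSite] = []
    for gi, group in enumerate(GROUPS):
        if group not in gen_groups:
            continue
        cfg = effects[group]
        for si in range(cfg.n_sites):
            rng = np.random.default_rng([seed, gi, si])
            params = _draw_site_params(cfg, rng)
            responses: dict[str, list[TrialSpikes]] = {}
            if silence_repeats > 0:
                responses[SILENCE_ID] = simulate_trials(
                    rate_profile(None, params, cfg),
                    silence_duration,
                    silence_repeats,
                    rng,
                    stimulus_id=SILENCE_ID,
                )
            if grid is not None:
                responses.update(_simulate_tone_grid(params, cfg, grid, rng))
            if speech is not None:
                for token in speech:
                    responses[speech_id(token.label)] = simulate_trials(
                        rate_profile(token, params, cfg),
                        SPEECH_SWEEP_MS,
                        token.n_repeats,
                        rng,
                        stimulus_id=speech_id(token.label),
                    )
            if train is not None:
                dur = train.onsets[-1] + train.period
                responses[BURST_ID] = simulate_trials(
                    rate_profile(train, params, cfg),
                    dur,
                    20,
                    rng,
                    stimulus_id=BURST_ID,
                )
            animal = si * cfg.n_animals // cfg.n_sites
            sites.append(
                RecordingSite(
                    site_id=f"{group}-{si:04d}",
                    group=group,
                    animal_id=f"{group}-r{animal:02d}",
                    depth_um=params.depth,
                    responses=responses,
                    params=params,
                )
            )
    return Cohort(
        sites=sites,
        effects=dict(effects),
        seed=seed,
        grid=grid,
        speech=list(speech) if speech is not None else None,
        train=train,
        silence_repeats=silence_repeats,
        silence_duration=silence_duration,
    )
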