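"""Frequency response areas and receptive-field property extraction.

The frequency response area (FRA) is the spike-count matrix over the tone
frequency x intensity grid, counted in the (0, 32] ms tone window.  From it
the extractor recovers the classic receptive-field properties: response
threshold, characteristic frequency, bandwidths 10 and 40 dB above threshold,
and (from the pooled tone PSTH) onset, peak, and end-of-peak latencies.

The extraction recipe — 3x3 median smoothing, a response criterion of the
expected spontaneous count plus ``max(1, 0.2 * (peak - spontaneous))``, and a
run of at least two adjacent supra-criterion frequencies — is standard FRA
practice; every constant is an argument so other labs' criteria can be
matched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import median_filter
from scipy.stats import spearmanr

from .core import RecordingSite
from .metrics import PSTH, window_counts
from .stimuli import ToneGrid, tone_id

__all__ = [
    "FrequencyResponseArea",
    "ReceptiveField",
    "build_fra",
    "extract_rf",
    "latency_metrics",
    "tonotopy_summary",
    "first_spike_onset_latency",
]

TONE_WINDOW = (0.0, 32.0)


@dataclass
class FrequencyResponseArea:
    """Spike counts per (frequency, intensity) grid cell in the tone window."""

    counts: np.ndarray  # shape (n_frequencies, n_intensities)
    grid: ToneGrid
    window: tuple[float, float] = TONE_WINDOW

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != self.grid.shape:
            raise ValueError(
                f"counts shape {self.counts.shape} does not match grid "
                f"shape {self.grid.shape}"
            )
        if np.any(self.counts < 0):
            raise ValueError("FRA counts must be non-negative")


@dataclass
class ReceptiveField:
    """Extracted receptive-field properties; NaN marks undefined fields."""

    cf: float  # Hz
    threshold: float  # dB SPL
    bw10: float  # octaves
    bw40: float  # octaves
    onset_latency: float  # ms
    peak_latency: float  # ms
    end_of_peak: float  # ms
    spontaneous_rate: float  # Hz
    responsive: bool


def build_fra(
    site: RecordingSite, grid: ToneGrid, window: tuple[float, float] = TONE_WINDOW
) -> FrequencyResponseArea:
    """Count in-window spikes for every grid tone (mean over presentations)."""
    nf, ni = grid.shape
    counts = np.zeros((nf, ni))
    missing = []
    for fi in range(nf):
        for ii in range(ni):
            sid = tone_id(grid.stimulus_index(fi, ii))
            trials = site.responses.get(sid)
            if not trials:
                missing.append((grid.frequencies[fi], grid.intensities[ii]))
                continue
            counts[fi, ii] = window_counts(trials, window, closed="right").mean()
    if missing:
        raise ValueError(
            f"site {site.site_id} is missing {len(missing)} grid tones, "
            f"first few (Hz, dB): {missing[:5]}"
        )
    return FrequencyResponseArea(counts=counts, grid=grid, window=window)


def _runs(mask: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """(start, stop) index pairs of True runs of length >= min_len (stop exclusive)."""
    runs = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            if i - start >= min_len:
                runs.append((start, i))
            start = None
    if start is not None and mask.size - start >= min_len:
        runs.append((start, mask.size))
    return runs


def _band_extent(
    row: np.ndarray, criterion: float, cf_index: int, octave_step: float
) -> float:
    """Octave extent of the supra-criterion run containing (or nearest) the CF."""
    runs = _runs(row >= criterion, 1)
    if not runs:
        return np.nan
    containing = [r for r in runs if r[0] <= cf_index < r[1]]
    if containing:
        lo, hi = containing[0]
    else:
        lo, hi = min(runs, key=lambda r: min(abs(r[0] - cf_index),
                                             abs(r[1] - 1 - cf_index)))
    return (hi - 1 - lo) * octave_step


def extract_rf(
    fra: FrequencyResponseArea,
    spontaneous: float,
    *,
    smooth_size: int = 3,
    criterion_fraction: float = 0.2,
    criterion_floor: float = 1.0,
    min_run: int = 2,
    criterion: float | None = None,
    latencies: tuple[float, float, float] | None = None,
) -> ReceptiveField:
    """Extract threshold, CF, and bandwidths from a frequency response area.

    The FRA is smoothed with a ``smooth_size`` x ``smooth_size`` median filter;
    the response criterion is the expected spontaneous count in the tone
    window plus ``max(criterion_floor, 2 * sqrt(spontaneous count),
    criterion_fraction * (smoothed max - spontaneous count))`` (or
    ``criterion`` verbatim when given).  The
    threshold is the lowest intensity whose smoothed row holds a run of at
    least ``min_run`` adjacent supra-criterion frequencies; the CF is the
    geometric-mean frequency of that run; BW10/BW40 are the octave extents of
    the supra-criterion runs 10 and 40 dB above threshold (NaN when off-grid),
    measured on a frequency-only median so smoothing across intensities does
    not erode the band edges.
    An unresponsive FRA yields ``responsive=False`` with NaN fields.

    ``latencies`` (onset, peak, end-of-peak) may be supplied from
    :func:`latency_metrics`; they are carried through into the result.
    """
    grid = fra.grid
    w0, w1 = fra.window
    spont_count = spontaneous * (w1 - w0) / 1000.0
    smoothed = median_filter(fra.counts, size=smooth_size, mode="nearest")
    # Bandwidths are measured on a frequency-only median so that the band
    # edges are not eroded by smoothing across intensity rows.
    smoothed_freq = median_filter(fra.counts, size=(smooth_size, 1), mode="nearest")
    if criterion is None:
        peak = float(smoothed.max())
        # the floor scales with the Poisson SD of the spontaneous count so
        # high-spontaneous sites are not flooded with false supra-criterion
        # cells below threshold
        criterion = spont_count + max(
            criterion_floor,
            2.0 * np.sqrt(spont_count),
            criterion_fraction * (peak - spont_count),
        )

    lat = latencies if latencies is not None else (np.nan, np.nan, np.nan)
    freqs = np.asarray(grid.frequencies)
    for ii, intensity in enumerate(grid.intensities):
        row = smoothed[:, ii]
        runs = _runs(row >= criterion, min_run)
        if not runs:
            continue
        # the run with the greatest summed response defines the CF
        lo, hi = max(runs, key=lambda r: row[r[0]: r[1]].sum())
        cf = float(2.0 ** np.mean(np.log2(freqs[lo:hi])))
        cf_index = int(np.argmin(np.abs(np.log2(freqs / cf))))
        db_step = grid.db_step or 5.0
        bws = []
        for offset in (10.0, 40.0):
            jj = ii + int(round(offset / db_step))
            if jj >= len(grid.intensities):
                bws.append(np.nan)
            else:
                bws.append(
                    _band_extent(smoothed_freq[:, jj], criterion, cf_index,
                                 grid.octave_step)
                )
        return ReceptiveField(
            cf=cf,
            threshold=float(intensity),
            bw10=bws[0],
            bw40=bws[1],
            onset_latency=lat[0],
            peak_latency=lat[1],
            end_of_peak=lat[2],
            spontaneous_rate=spontaneous,
            responsive=True,
        )
    return ReceptiveField(
        cf=np.nan, threshold=np.nan, bw10=np.nan, bw40=np.nan,
        onset_latency=np.nan, peak_latency=np.nan, end_of_peak=np.nan,
        spontaneous_rate=spontaneous, responsive=False,
    )


def latency_metrics(
    psth: PSTH, spontaneous: float, spont_sd: float | None = None
) -> tuple[float, float, float]:
    """Onset, peak, and end-of-peak latency (ms) from a pooled 1-ms PSTH.

    The criterion is the expected spontaneous count per bin plus twice its
    SD (Poisson ``sqrt`` unless ``spont_sd`` is given).  Onset is the left
    edge of the first of >= 2 consecutive supra-criterion bins; peak is the
    center of the maximum-count bin of that first excursion; end-of-peak is
    the left edge of the first bin after the peak falling below criterion.
    All NaN when no excursion exists.
    """
    expected = spontaneous * psth.n_trials * psth.bin_width / 1000.0
    sd = spont_sd if spont_sd is not None else np.sqrt(expected)
    crit = expected + 2.0 * sd
    above = psth.counts > crit
    runs = _runs(above, 2)
    if not runs:
        return (np.nan, np.nan, np.nan)
    lo, hi = runs[0]
    onset = float(psth.bin_edges[lo])
    peak_bin = lo + int(np.argmax(psth.counts[lo:hi]))
    peak = float(psth.bin_centers[peak_bin])
    end = np.nan
    for j in range(peak_bin + 1, psth.counts.size):
        if psth.counts[j] <= crit:
            end = float(psth.bin_edges[j])
            break
    return (onset, peak, end)


def first_spike_onset_latency(trials, t0: float = 0.0) -> float:
    """Median across trials of the first spike time after ``t0`` (NaN if none spike)."""
    firsts = []
    for tr in trials:
        after = tr.spike_times[tr.spike_times > t0]
        if after.size:
            firsts.append(after[0] - t0)
    return float(np.median(firsts)) if firsts else np.nan


#: Octave-band edges (kHz) of the five 1-octave summary bins.
_OCTAVE_BINS = (1.0, 2.0, 4.0, 8.0, 16.0, 32.0)


def tonotopy_summary(
    cfs: Sequence[float], depths: Sequence[float]
) -> tuple[float, np.ndarray]:
    """Tonotopy of one group: CF-vs-depth correlation and octave-bin occupancy.

    Returns the Spearman correlation of log2(CF) against recording depth and
    the percentage of responsive sites in each of the five 1-octave bins
    spanning 1-32 kHz (percentages sum to 100).
    """
    cfs = np.asarray(cfs, dtype=float)
    depths = np.asarray(depths, dtype=float)
    ok = np.isfinite(cfs) & np.isfinite(depths)
    cfs, depths = cfs[ok], depths[ok]
    if cfs.size < 3:
        raise ValueError(
            f"tonotopy_summary needs >= 3 responsive sites with depth, got {cfs.size}"
        )
    rho = float(spearmanr(np.log2(cfs), depths).statistic)
    edges = np.array(_OCTAVE_BINS) * 1000.0
    idx = np.clip(np.digitize(cfs, edges[1:-1]), 0, 4)
    counts = np.bincount(idx, minlength=5).astype(float)
    return rho, 100.0 * counts / counts.sum()
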