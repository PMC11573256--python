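"""Basic report plots: PSTHs and frequency-response-area heat maps."""

from __future__ import annotations

import numpy as np

from .metrics import PSTH
from .rf import FrequencyResponseArea


def plot_psth(psth: PSTH, ax=None, **bar_kwargs):
    """Bar plot of a PSTH's per-bin firing rate (Hz vs ms)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.bar(psth.bin_centers, psth.rate, width=psth.bin_width, align="center",
           **bar_kwargs)
    ax.set_xlabel("time from onset (ms)")
    ax.set_ylabel("rate (Hz)")
    return ax


def plot_fra(fra: FrequencyResponseArea, ax=None, **imshow_kwargs):
    """Heat map of an FRA (intensity on the y axis, log-spaced frequency on x)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    img = ax.imshow(
        fra.counts.T,
        origin="lower",
        aspect="auto",
        extent=(
            np.log2(fra.grid.frequencies[0] / 1000.0),
            np.log2(fra.grid.frequencies[-1] / 1000.0),
            fra.grid.intensities[0],
            fra.grid.intensities[-1],
        ),
        **imshow_kwargs,
    )
    ax.set_xlabel("frequency (octaves re 1 kHz)")
    ax.set_ylabel("intensity (dB SPL)")
    return img
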