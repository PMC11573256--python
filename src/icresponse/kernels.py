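"""Transient response kernels for the synthetic generator.

The driven component of an onset response is modeled as an alpha-like bump
with compact support: it is zero up to the onset latency, rises to 1 at the
peak latency, and returns to zero at the end-of-peak latency.  Using a
compactly supported bump (rather than a literal alpha function, which decays
only asymptotically) lets the latency extractor recover all three latencies
exactly in the noiseless limit.
"""

from __future__ import annotations

import numpy as np

__all__ = ["bump", "bump_integral", "bump_phase_resultant"]


def bump(t: np.ndarray, onset: float, peak: float, end: float) -> np.ndarray:
    """Unit-peak transient supported on (onset, end) with maximum at ``peak``.

    k(t) = u**2 * v**beta with u = (t-onset)/(peak-onset),
    v = (end-t)/(end-peak) and beta = 2*(end-peak)/(peak-onset), which places
    the stationary point exactly at ``peak`` and normalizes k(peak) = 1.
    """
    if not (onset < peak < end):
        raise ValueError(f"need onset < peak < end, got ({onset}, {peak}, {end})")
    t = np.asarray(t, dtype=float)
    rise = peak - onset
    fall = end - peak
    beta = 2.0 * fall / rise
    u = (t - onset) / rise
    v = (end - t) / fall
    inside = (t > onset) & (t < end)
    out = np.zeros_like(t)
    out[inside] = u[inside] ** 2 * v[inside] ** beta
    return out


def bump_integral(onset: float, peak: float, end: float, n: int = 4001) -> float:
    """Integral of the unit-peak bump over its support, in ms."""
    t = np.linspace(onset, end, n)
    return float(np.trapezoid(bump(t, onset, peak, end), t))


def bump_phase_resultant(
    onset: float, peak: float, end: float, period: float, n: int = 4001
) -> float:
    """Resultant length of the bump's mass treated as phases of ``period`` ms.

    This is the vector strength an ideal, noiseless burst-locked response
    with this transient shape would attain.
    """
    t = np.linspace(onset, end, n)
    w = bump(t, onset, peak, end)
    ph = 2.0 * np.pi * (t % period) / period
    c = np.trapezoid(w * np.cos(ph), t)
    s = np.trapezoid(w * np.sin(ph), t)
    total = np.trapezoid(w, t)
    return float(np.hypot(c, s) / total)
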