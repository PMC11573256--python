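"""Group-comparison statistics.

The statistical layer mirrors the recorded-cohort analysis: Kolmogorov–
Smirnov (Lilliefors) normality screening per group, a Kruskal–Wallis omnibus
test, uncorrected pairwise two-sided Mann–Whitney U tests (exact for small
tie-free samples, normal approximation with tie correction otherwise), and —
for receptive-field properties — the classic Brown–Forsythe heteroscedastic
ANOVA, F* with k-1 numerator df and Satterthwaite denominator df.  The
analysis unit is the recording site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparison",
    "compare_groups",
    "percent_change",
    "mann_whitney",
    "brown_forsythe_anova",
]


@dataclass
class GroupSummary:
    n: int
    mean: float
    median: float
    sd: float
    se: float


@dataclass
class PairwiseTest:
    pair: tuple[str, str]
    statistic: float  # Mann-Whitney U of the first group
    p: float
    p_adjusted: float | None = None


@dataclass
class GroupComparison:
    """Full comparison report for one metric across groups."""

    metric: str
    family: str
    groups: dict[str, GroupSummary]
    normality: dict[str, float]  # per-group KS (Lilliefors) p
    omnibus: tuple[str, float, float]  # (test name, statistic, p)
    pairwise: list[PairwiseTest] = field(default_factory=list)
    omnibus_df: tuple[float, float] | None = None


def _all_identical(*arrays: np.ndarray) -> bool:
    pooled = np.concatenate(arrays)
    return bool(pooled.size) and bool(np.all(pooled == pooled[0]))


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney U (U of the first sample) and p value.

    Exact when both samples have n <= 20 and the pooled data are tie-free;
    otherwise the normal approximation with tie correction.  Degenerate input
    (every value identical in both groups) returns p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("mann_whitney requires non-empty samples")
    if _all_identical(x, y):
        return float(x.size * y.size / 2.0), 1.0
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size <= 20 and y.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def brown_forsythe_anova(groups: Sequence[np.ndarray]) -> tuple[float, float, float, float]:
    """Classic Brown–Forsythe heteroscedastic ANOVA on group means.

    F* = sum n_i (m_i - m)^2 / sum (1 - n_i / N) s_i^2, compared to an F
    distribution with k - 1 and Satterthwaite-adjusted denominator degrees of
    freedom.  Returns (F, df_num, df_denom, p).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2 or any(g.size < 2 for g in groups):
        raise ValueError("brown_forsythe_anova needs >= 2 groups with n >= 2")
    ns = np.array([g.size for g in groups], dtype=float)
    n_total = ns.sum()
    means = np.array([g.mean() for g in groups])
    variances = np.array([g.var(ddof=1) for g in groups])
    grand = np.concatenate(groups).mean()
    num = float(np.sum(ns * (means - grand) ** 2))
    weights = (1.0 - ns / n_total) * variances
    denom = float(weights.sum())
    if denom == 0.0:
        return np.nan, float(k - 1), np.nan, 1.0
    f_star = num / denom
    c = weights / denom
    df_denom = 1.0 / float(np.sum(c ** 2 / (ns - 1.0)))
    df_num = float(k - 1)
    p = float(sps.f.sf(f_star, df_num, df_denom))
    return f_star, df_num, df_denom, p


def _normality_p(values: np.ndarray) -> float:
    if np.unique(values).size < 2 or values.size < 4:
        return np.nan
    _, p = lilliefors(values, dist="norm")
    return float(min(max(p, 0.0), 1.0))


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]],
    metric: str,
    family: str = "nonparametric",
    holm: bool = False,
    min_n: int = 3,
) -> GroupComparison:
    """Compare one metric across groups.

    ``family="nonparametric"``: per-group KS (Lilliefors) normality p,
    Kruskal–Wallis omnibus, and all pairwise two-sided Mann–Whitney U tests
    (uncorrected by default; ``holm=True`` adds Holm-adjusted p values).
    ``family="brown_forsythe"``: the heteroscedastic ANOVA used for
    receptive-field properties (omnibus only).
    """
    if family not in ("nonparametric", "brown_forsythe"):
        raise ValueError(f"unknown family {family!r}")
    arrays = {
        g: np.asarray(v, dtype=float)[~np.isnan(np.asarray(v, dtype=float))]
        for g, v in values_by_group.items()
    }
    if len(arrays) < 2:
        raise ValueError("compare_groups needs >= 2 groups")
    for g, v in arrays.items():
        if v.size < min_n:
            raise ValueError(f"group {g!r} has n={v.size} < {min_n}")

    summaries = {
        g: GroupSummary(
            n=int(v.size),
            mean=float(v.mean()),
            median=float(np.median(v)),
            sd=float(v.std(ddof=1)),
            se=float(v.std(ddof=1) / np.sqrt(v.size)),
        )
        for g, v in arrays.items()
    }
    normality = {g: _normality_p(v) for g, v in arrays.items()}

    if family == "brown_forsythe":
        f_star, df_num, df_denom, p = brown_forsythe_anova(list(arrays.values()))
        return GroupComparison(
            metric=metric,
            family=family,
            groups=summaries,
            normality=normality,
            omnibus=("brown_forsythe_anova", f_star, p),
            omnibus_df=(df_num, df_denom),
        )

    if _all_identical(*arrays.values()):
        omnibus = ("kruskal_wallis", 0.0, 1.0)
    else:
        h, p = sps.kruskal(*arrays.values())
        omnibus = ("kruskal_wallis", float(h), float(p))

    pairwise = []
    for a, b in combinations(arrays, 2):
        u, p = mann_whitney(arrays[a], arrays[b])
        pairwise.append(PairwiseTest(pair=(a, b), statistic=u, p=p))
    if holm and pairwise:
        adjusted = multipletests([t.p for t in pairwise], method="holm")[1]
        for t, p_adj in zip(pairwise, adjusted):
            t.p_adjusted = float(p_adj)

    return GroupComparison(
        metric=metric,
        family=family,
        groups=summaries,
        normality=normality,
        omnibus=omnibus,
        pairwise=pairwise,
    )


def percent_change(reference_mean: float, test_mean: float) -> float:
    """Signed percent change of ``test_mean`` relative to ``reference_mean``."""
    if reference_mean == 0:
        raise ValueError("percent_change is undefined for a zero reference mean")
    return 100.0 * (test_mean - reference_mean) / reference_mean
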