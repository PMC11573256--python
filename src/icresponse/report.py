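"""End-to-end cohort analysis: per-site metrics, group comparisons, report bundle.

``run_full_analysis`` runs every stage the stimulus catalog supports —
speech driven rates over the whole/consonant/vowel windows, nearest-neighbor
consonant and vowel discrimination, tone response strength, receptive-field
extraction, and noise-burst metrics — then compares each metric across groups
and summarizes the headline percent-change contrasts (VNS-tone vs VPA and
VNS-speech vs VPA on the whole-window speech driven rate).
"""

from __future__ import annotations

import dataclasses
import json
import os
import zlib
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .classify import consonant_discrimination, vowel_discrimination
from .config import AnalysisConfig
from .core import Cohort, RecordingSite
from .metrics import driven_rate, spontaneous_rate_estimate, tone_response_strength
from .metrics import compute_psth
from .rf import build_fra, extract_rf, latency_metrics, tonotopy_summary
from .stats import GroupComparison, compare_groups, percent_change
from .stimuli import BURST_ID, SILENCE_ID, speech_id, tone_id
from .temporal import compute_temporal_metrics

__all__ = ["run_full_analysis", "ReportBundle", "PipelineError", "site_speech_rate"]

#: The seven standard comparison blocks and the site-metric column each summarizes.
COMPARISON_COLUMNS = {
    "speech_whole": "speech_rate_400ms",
    "speech_consonant": "speech_rate_40ms",
    "speech_vowel": "speech_rate_300ms",
    "classifier_consonant": "classifier_consonant_acc",
    "classifier_vowel": "classifier_vowel_acc",
    "tone_strength": "tone_spikes_per_tone",
    "burst": "burst_spikes_per_burst",
}

RF_COLUMNS = (
    "rf_threshold", "rf_bw10", "rf_bw40", "rf_onset_latency",
    "rf_peak_latency", "rf_end_of_peak", "spontaneous_hz",
)


class PipelineError(RuntimeError):
    """A stage of the full analysis failed; the stage name is recorded."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"analysis stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class ReportBundle:
    """All outputs of one full-analysis run."""

    site_metrics: pd.DataFrame
    comparisons: dict[str, GroupComparison]
    burst_comparisons: dict[str, GroupComparison]
    rf_comparisons: dict[str, GroupComparison]
    percent_changes: dict[str, float]
    tonotopy: dict[str, dict[str, Any]]
    manifest: dict = field(default_factory=dict)

    def comparison_blocks(self) -> list[str]:
        return list(self.comparisons)


def _tie_seed(config_seed: int, site_id: str, tag: str) -> int:
    return (zlib.crc32(f"{site_id}:{tag}".encode()) ^ config_seed) & 0x7FFFFFFF


def site_speech_rate(
    site: RecordingSite,
    cohort: Cohort,
    window: tuple[float, float],
    spontaneous: float,
) -> float:
    """Mean driven rate over all speech tokens for one window (Hz)."""
    if cohort.speech is None:
        raise ValueError("cohort has no speech responses")
    rates = [
        driven_rate(site.responses[speech_id(tok.label)], window, spontaneous)
        for tok in cohort.speech
    ]
    return float(np.mean(rates))


def _site_row(
    site: RecordingSite, cohort: Cohort, config: AnalysisConfig
) -> dict[str, Any]:
    row: dict[str, Any] = {
        "site_id": site.site_id,
        "group": site.group,
        "animal_id": site.animal_id,
        "depth_um": site.depth_um,
    }
    spont = (
        spontaneous_rate_estimate(
            site.responses[SILENCE_ID], (0.0, cohort.silence_duration)
        )
        if SILENCE_ID in site.responses
        else 0.0
    )
    row["spontaneous_hz"] = spont

    if cohort.speech is not None:
        for name, window in (
            ("speech_rate_400ms", config.speech_whole_window),
            ("speech_rate_40ms", config.consonant_window),
            ("speech_rate_300ms", config.vowel_window),
        ):
            row[name] = site_speech_rate(site, cohort, window, spont)
        speech_responses = {
            speech_id(t.label): site.responses[speech_id(t.label)]
            for t in cohort.speech
        }
        labels = {t.label for t in cohort.speech}
        if {"chad", "dad", "fad", "gad", "had", "jad", "sad", "shad", "tad"} <= labels:
            row["classifier_consonant_acc"] = consonant_discrimination(
                speech_responses,
                tie_seed=_tie_seed(config.seed, site.site_id, "cons"),
                tie_mode=config.classifier_tie_mode,
            ).mean_accuracy
        if {"dad", "deed", "dood"} <= labels:
            row["classifier_vowel_acc"] = vowel_discrimination(
                speech_responses,
                tie_seed=_tie_seed(config.seed, site.site_id, "vowel"),
                tie_mode=config.classifier_tie_mode,
            ).mean_accuracy

    if cohort.grid is not None:
        tone_trials = [
            site.responses[tone_id(k)] for k in range(cohort.grid.n_stimuli)
        ]
        row["tone_spikes_per_tone"] = tone_response_strength(
            tone_trials, config.tone_window
        )
        fra = build_fra(site, cohort.grid, config.tone_window)
        pooled = [tr for trials in tone_trials for tr in trials]
        psth = compute_psth(pooled, bin=1.0, window=(0.0, 50.0))
        lat = latency_metrics(psth, spont)
        rec = extract_rf(
            fra,
            spont,
            smooth_size=config.rf_smooth_size,
            criterion_fraction=config.rf_criterion_fraction,
            criterion_floor=config.rf_criterion_floor,
            min_run=config.rf_min_run,
            latencies=lat,
        )
        row["rf_responsive"] = rec.responsive
        row["rf_cf_hz"] = rec.cf
        row["rf_threshold"] = rec.threshold
        row["rf_bw10"] = rec.bw10
        row["rf_bw40"] = rec.bw40
        row["rf_onset_latency"] = rec.onset_latency
        row["rf_peak_latency"] = rec.peak_latency
        row["rf_end_of_peak"] = rec.end_of_peak

    if cohort.train is not None:
        tm = compute_temporal_metrics(
            site.responses[BURST_ID],
            cohort.train,
            spontaneous=spont,
            response_window=config.burst_response_window,
        )
        row["burst_spikes_per_burst"] = tm.driven_spikes_per_burst
        row["burst_onset_ms"] = tm.onset_latency
        row["burst_peak_ms"] = tm.peak_latency
        row["burst_vector_strength"] = tm.vector_strength
        row["burst_rayleigh"] = tm.rayleigh
        row["burst_n_spikes"] = tm.n_spikes
    return row


def _by_group(df: pd.DataFrame, column: str) -> dict[str, np.ndarray]:
    return {
        g: sub[column].to_numpy()
        for g, sub in df.groupby("group", sort=False)
    }


def _compare(df, column, metric, family="nonparametric", holm=False):
    cmp = compare_groups(_by_group(df, column), metric=metric, family=family,
                         holm=holm)
    return cmp


def run_full_analysis(
    cohort: Cohort,
    config: AnalysisConfig | None = None,
    out_dir: str | None = None,
) -> ReportBundle:
    """Run every supported analysis stage on ``cohort``.

    Stages whose stimuli are absent from the catalog are skipped; with the
    full catalog the report holds the seven standard comparison blocks plus
    the receptive-field property block.  Any stage failure raises
    :class:`PipelineError` naming the stage, and nothing is written.  With
    ``out_dir`` the bundle is written as ``site_metrics.csv``,
    ``comparisons.json``, and ``manifest.json`` after all stages succeed.
    """
    config = config or AnalysisConfig()

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as err:  # noqa: BLE001 - rewrap with stage name
            raise PipelineError(name, err) from err

    rows = stage(
        "site_metrics",
        lambda: [_site_row(s, cohort, config) for s in cohort.sites],
    )
    df = pd.DataFrame(rows)

    multi_group = df["group"].nunique() >= 2
    comparisons: dict[str, GroupComparison] = {}
    burst_comparisons: dict[str, GroupComparison] = {}
    rf_comparisons: dict[str, GroupComparison] = {}
    pct: dict[str, float] = {}
    tonotopy: dict[str, dict[str, Any]] = {}

    if multi_group:
        for block, column in COMPARISON_COLUMNS.items():
            if column not in df.columns:
                continue
            comparisons[block] = stage(
                f"compare:{block}",
                _compare, df, column, column,
                config.stats_family, config.stats_holm,
            )
        if "burst_spikes_per_burst" in df.columns:
            for name, column in (
                ("driven_spikes", "burst_spikes_per_burst"),
                ("onset_latency", "burst_onset_ms"),
                ("peak_latency", "burst_peak_ms"),
                ("vector_strength", "burst_vector_strength"),
            ):
                burst_comparisons[name] = stage(
                    f"compare:burst_{name}", _compare, df, column, column,
                )
        if "rf_threshold" in df.columns:
            for column in RF_COLUMNS:
                rf_comparisons[column] = stage(
                    f"compare:rf:{column}",
                    _compare, df, column, column, "brown_forsythe",
                )

    if "speech_rate_400ms" in df.columns and multi_group:
        means = df.groupby("group")["speech_rate_400ms"].mean()
        if "vpa" in means:
            for test_group in ("vpa_vns_tone", "vpa_vns_speech"):
                if test_group in means:
                    pct[f"{test_group}_vs_vpa_speech_400ms"] = stage(
                        "percent_change",
                        percent_change, means["vpa"], means[test_group],
                    )

    if "rf_cf_hz" in df.columns:
        for g, sub in df.groupby("group", sort=False):
            ok = sub[sub.get("rf_responsive", False) == True]  # noqa: E712
            if len(ok) >= 3:
                rho, pcts = stage(
                    f"tonotopy:{g}", tonotopy_summary,
                    ok["rf_cf_hz"].to_numpy(), ok["depth_um"].to_numpy(),
                )
                tonotopy[g] = {
                    "cf_depth_spearman": rho,
                    "percent_per_octave_bin": list(pcts),
                }

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.hash,
        "cohort_seed": cohort.seed,
        "group_counts": cohort.group_counts(),
        "n_comparison_blocks": len(comparisons),
        "source": {
            "table": "site_metrics.csv",
            "rows_by_group": cohort.group_counts(),
            "columns": {k: v for k, v in COMPARISON_COLUMNS.items()
                        if v in df.columns},
        },
    }
    bundle = ReportBundle(
        site_metrics=df,
        comparisons=comparisons,
        burst_comparisons=burst_comparisons,
        rf_comparisons=rf_comparisons,
        percent_changes=pct,
        tonotopy=tonotopy,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_bundle(bundle, out_dir)
    return bundle


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def _write_bundle(bundle: ReportBundle, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    bundle.site_metrics.to_csv(
        os.path.join(out_dir, "site_metrics.csv"), index=False,
        float_format="%.6g",
    )
    doc = {
        "comparisons": _jsonable(bundle.comparisons),
        "burst_comparisons": _jsonable(bundle.burst_comparisons),
        "rf_comparisons": _jsonable(bundle.rf_comparisons),
        "percent_changes": _jsonable(bundle.percent_changes),
        "tonotopy": _jsonable(bundle.tonotopy),
    }
    with open(os.path.join(out_dir, "comparisons.json"), "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(_jsonable(bundle.manifest), fh, indent=2, sort_keys=True)
        fh.write("\n")
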