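"""Cohort serialization: a diff-able CSV + JSON on-disk layout.

A cohort directory holds::

    manifest.json   # schema version, seed, group config, stimulus catalog
    sites.csv       # one row per site (metadata + generator ground truth)
    spikes.csv      # one row per spike:
                    # site_id,group,animal_id,depth_um,stimulus_id,repeat_index,spike_time_ms

Spike times are canonicalized to four fraction digits so a write/read/write
round trip is byte-identical.  Repeats with no spikes are reconstructed from
the per-stimulus repeat counts recorded in the manifest.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import asdict

import numpy as np

from .config import config_hash
from .cohort import GroupEffectConfig, SiteParams
from .core import Cohort, RecordingSite, TrialSpikes
from .stimuli import (
    BURST_ID,
    SILENCE_ID,
    SpeechToken,
    build_noise_train,
    build_tone_grid,
    speech_id,
    tone_id,
)

__all__ = ["write_cohort", "read_cohort", "CohortFormatError", "SCHEMA_VERSION"]

SCHEMA_VERSION = "1"

_PARAM_FIELDS = (
    "cf", "threshold", "bw10", "bw40", "onset_latency", "peak_latency",
    "end_of_peak", "spontaneous_rate", "depth", "peak_driven_rate",
)


class CohortFormatError(ValueError):
    """Raised for malformed or incompatible cohort directories."""


def _manifest(cohort: Cohort) -> dict:
    stimuli: dict = {}
    if cohort.grid is not None:
        g = cohort.grid
        stimuli["tone_grid"] = {
            "f_lo": g.frequencies[0],
            "f_hi": g.frequencies[-1],
            "octave_step": g.octave_step,
            "db_lo": g.intensities[0],
            "db_hi": g.intensities[-1],
            "db_step": g.db_step,
            "n_stimuli": g.n_stimuli,
        }
    if cohort.speech is not None:
        stimuli["speech"] = [
            {
                "label": t.label,
                "n_repeats": t.n_repeats,
                "consonant_window": list(t.consonant_window),
                "vowel_window": list(t.vowel_window),
                "whole_window": list(t.whole_window),
            }
            for t in cohort.speech
        ]
    if cohort.train is not None:
        stimuli["noise_train"] = {
            "rate": cohort.train.rate,
            "n_bursts": cohort.train.n_bursts,
            "burst_duration": cohort.train.burst_duration,
            "n_repeats": _burst_repeats(cohort),
        }
    stimuli["silence"] = {
        "n_repeats": cohort.silence_repeats,
        "duration_ms": cohort.silence_duration,
    }
    effects = {g: asdict(c) for g, c in sorted(cohort.effects.items())}
    body = {
        "schema_version": SCHEMA_VERSION,
        "seed": cohort.seed,
        "effects": effects,
        "stimuli": stimuli,
        "group_counts": dict(sorted(cohort.group_counts().items())),
    }
    body["config_hash"] = config_hash(
        {"effects": effects, "stimuli": stimuli, "seed": cohort.seed}
    )
    return body


def _burst_repeats(cohort: Cohort) -> int:
    for site in cohort.sites:
        if BURST_ID in site.responses:
            return len(site.responses[BURST_ID])
    return 20


def write_cohort(cohort: Cohort, path: str) -> None:
    """Write ``cohort`` to directory ``path`` (created if absent)."""
    os.makedirs(path, exist_ok=True)
    with open(os.path.join(path, "manifest.json"), "w") as fh:
        json.dump(_manifest(cohort), fh, indent=2, sort_keys=True)
        fh.write("\n")

    with open(os.path.join(path, "sites.csv"), "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(
            ["site_id", "group", "animal_id", "depth_um"]
            + [f"gt_{f}" for f in _PARAM_FIELDS]
        )
        for site in cohort.sites:
            row = [site.site_id, site.group, site.animal_id, f"{site.depth_um:.1f}"]
            if site.params is not None:
                row += [f"{getattr(site.params, f):.6g}" for f in _PARAM_FIELDS]
            else:
                row += [""] * len(_PARAM_FIELDS)
            writer.writerow(row)

    with open(os.path.join(path, "spikes.csv"), "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(
            ["site_id", "group", "animal_id", "depth_um", "stimulus_id",
             "repeat_index", "spike_time_ms"]
        )
        for site in cohort.sites:
            depth = f"{site.depth_um:.1f}"
            for sid in site.responses:
                for trial in site.responses[sid]:
                    for t in trial.spike_times:
                        writer.writerow(
                            [site.site_id, site.group, site.animal_id, depth,
                             sid, trial.repeat_index, f"{t:.4f}"]
                        )


def _stimulus_plan(manifest: dict) -> list[tuple[str, int]]:
    """(stimulus_id, n_repeats) for every stimulus in manifest order."""
    stimuli = manifest["stimuli"]
    plan: list[tuple[str, int]] = []
    silence = stimuli.get("silence", {})
    if silence.get("n_repeats", 0) > 0:
        plan.append((SILENCE_ID, silence["n_repeats"]))
    if "tone_grid" in stimuli:
        for k in range(stimuli["tone_grid"]["n_stimuli"]):
            plan.append((tone_id(k), 1))
    for tok in stimuli.get("speech", []):
        plan.append((speech_id(tok["label"]), tok["n_repeats"]))
    if "noise_train" in stimuli:
        plan.append((BURST_ID, stimuli["noise_train"]["n_repeats"]))
    return plan


def read_cohort(path: str) -> Cohort:
    """Read a cohort directory written by :func:`write_cohort`."""
    manifest_path = os.path.join(path, "manifest.json")
    try:
        with open(manifest_path) as fh:
            manifest = json.load(fh)
    except FileNotFoundError:
        raise CohortFormatError(f"no manifest.json in {path}") from None
    version = manifest.get("schema_version")
    if version != SCHEMA_VERSION:
        raise CohortFormatError(
            f"schema version mismatch: file has {version!r}, "
            f"this reader expects {SCHEMA_VERSION!r}"
        )

    stimuli = manifest["stimuli"]
    grid = None
    if "tone_grid" in stimuli:
        g = stimuli["tone_grid"]
        grid = build_tone_grid(
            g["f_lo"], g["f_hi"], g["octave_step"], g["db_lo"], g["db_hi"],
            g["db_step"],
        )
    speech = None
    if "speech" in stimuli:
        speech = [
            SpeechToken(
                label=t["label"],
                consonant_window=tuple(t["consonant_window"]),
                vowel_window=tuple(t["vowel_window"]),
                whole_window=tuple(t["whole_window"]),
                n_repeats=t["n_repeats"],
            )
            for t in stimuli["speech"]
        ]
    train = None
    if "noise_train" in stimuli:
        tr = stimuli["noise_train"]
        train = build_noise_train(tr["rate"], tr["n_bursts"], tr["burst_duration"])

    effects = {
        g: GroupEffectConfig(**cfg) for g, cfg in manifest["effects"].items()
    }

    sites: dict[str, RecordingSite] = {}
    sites_path = os.path.join(path, "sites.csv")
    with open(sites_path, newline="") as fh:
        for row in csv.DictReader(fh):
            params = None
            if row.get("gt_cf"):
                params = SiteParams(
                    **{f: float(row[f"gt_{f}"]) for f in _PARAM_FIELDS}
                )
            sites[row["site_id"]] = RecordingSite(
                site_id=row["site_id"],
                group=row["group"],
                animal_id=row["animal_id"],
                depth_um=float(row["depth_um"]),
                responses={},
                params=params,
            )

    # accumulate spike times per (site, stimulus, repeat)
    acc: dict[str, dict[str, dict[int, list[float]]]] = {
        sid: {} for sid in sites
    }
    spikes_path = os.path.join(path, "spikes.csv")
    with open(spikes_path, newline="") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            try:
                t = float(row["spike_time_ms"])
                rep = int(row["repeat_index"])
            except (TypeError, ValueError) as err:
                raise CohortFormatError(
                    f"{spikes_path}:{lineno}: malformed spike row {row}"
                ) from err
            if t < 0:
                raise CohortFormatError(
                    f"{spikes_path}:{lineno}: negative spike time {t} "
                    f"(site {row['site_id']}, stimulus {row['stimulus_id']})"
                )
            if row["site_id"] not in acc:
                raise CohortFormatError(
                    f"{spikes_path}:{lineno}: unknown site {row['site_id']!r}"
                )
            acc[row["site_id"]].setdefault(row["stimulus_id"], {}).setdefault(
                rep, []
            ).append(t)

    plan = _stimulus_plan(manifest)
    for sid, site in sites.items():
        for stim_id, n_rep in plan:
            per_rep = acc[sid].get(stim_id, {})
            site.responses[stim_id] = [
                TrialSpikes(
                    np.sort(np.asarray(per_rep.get(r, []), dtype=float)),
                    stimulus_id=stim_id,
                    repeat_index=r,
                )
                for r in range(n_rep)
            ]

    silence = stimuli.get("silence", {})
    return Cohort(
        sites=list(sites.values()),
        effects=effects,
        seed=manifest["seed"],
        grid=grid,
        speech=speech,
        train=train,
        silence_repeats=silence.get("n_repeats", 0),
        silence_duration=silence.get("duration_ms", 400.0),
    )
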