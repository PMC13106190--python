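"""Plain-text persistence: per-recording CSV, cohort manifest, feature tables.

One recording is a CSV with columns ``time_s,ax,ay,az``; the cohort manifest
is a JSON list of per-recording metadata (subject, task, side, sampling
rate, age, gender, raw score, file path, and — for synthetic cohorts — the
ground-truth peak indices).  Feature tables are wide CSVs accompanied by the
feature-schema manifest.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import build_schema
from .simulate import Recording

__all__ = [
    "write_cohort",
    "load_cohort",
    "read_recording_csv",
    "write_features",
    "read_features",
    "load_run_config",
]

MANIFEST_NAME = "manifest.json"


def write_cohort(recordings: list[Recording], out_dir: str | Path) -> Path:
    """Write one CSV per recording plus a manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in recordings:
        fname = f"{rec.record_id}.csv"
        t = np.arange(len(rec.samples)) / rec.fs
        df = pd.DataFrame({"time_s": t, "ax": rec.samples[:, 0],
                           "ay": rec.samples[:, 1], "az": rec.samples[:, 2]})
        df.to_csv(out / fname, index=False, float_format="%.6f")
        entries.append({
            "subject_id": rec.subject_id, "task": rec.task, "side": rec.side,
            "fs": rec.fs, "age": rec.age, "gender": rec.gender,
            "score_raw": rec.score_raw, "path": fname,
            "ground_truth_peaks": (None if rec.ground_truth_peaks is None
                                   else [int(i) for i in rec.ground_truth_peaks]),
        })
    manifest = out / MANIFEST_NAME
    manifest.write_text(json.dumps(entries, indent=1, sort_keys=True))
    return manifest


def read_recording_csv(path: str | Path, column_map: dict[str, str] | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Read a triaxial CSV; returns (time_s, samples (n, 3)).

    `column_map` renames foreign column headers onto the native dialect,
    e.g. ``{"t": "time_s", "acc_x": "ax", ...}``.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = {"time_s", "ax", "ay", "az"} - set(df.columns)
    if missing:
        raise ValueError(f"recording CSV missing columns {sorted(missing)}")
    return df["time_s"].to_numpy(), df[["ax", "ay", "az"]].to_numpy(dtype=float)


def load_cohort(manifest_path: str | Path) -> list[Recording]:
    manifest_path = Path(manifest_path)
    entries = json.loads(manifest_path.read_text())
    out = []
    for e in entries:
        _, samples = read_recording_csv(manifest_path.parent / e["path"])
        gt = e.get("ground_truth_peaks")
        out.append(Recording(
            subject_id=e["subject_id"], task=e["task"], side=e["side"],
            fs=e["fs"], samples=samples, age=e["age"], gender=e["gender"],
            score_raw=e["score_raw"],
            ground_truth_peaks=None if gt is None else np.asarray(gt, int)))
    return out


def write_features(table: pd.DataFrame, out_path: str | Path) -> None:
    """Write a feature table plus its schema manifest (`<stem>.schema.json`)."""
    out_path = Path(out_path)
    table.to_csv(out_path, index=False)
    schema_path = out_path.with_suffix(".schema.json")
    schema_path.write_text(json.dumps(build_schema(), indent=1))


def read_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


_RUN_CONFIG_KEYS = {"task", "side", "scenario", "seed", "budget",
                    "inner_splits", "max_greedy", "bootstrap_reps",
                    "eligibility_delta", "global_selection", "spaces"}


def load_run_config(path: str | Path) -> dict:
    """Read a JSON or YAML run configuration for the selection pipeline.

    Recognised keys: task, side, scenario, seed, budget, inner_splits,
    max_greedy, bootstrap_reps, eligibility_delta, global_selection, and `spaces`
    (per-model hyperparameter grid overrides, e.g. to pin previously tuned
    settings).  Unknown keys raise.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yml", ".yaml"):
        import yaml
        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    if not isinstance(cfg, dict):
        raise ValueError("run config must be a mapping")
    unknown = set(cfg) - _RUN_CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown run-config keys: {sorted(unknown)}")
    return cfg
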