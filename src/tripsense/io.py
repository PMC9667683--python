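"""CSV interchange formats and the reproducibility manifest.

All tabular interchange is plain CSV with documented headers, UTF-8,
ISO-8601 timestamps; configuration is YAML and manifests are JSON.
Streams are written one file per sensor: ``fixes.csv``, ``epochs.csv``,
``rr.csv``, plus ``timetable.csv`` and ``participants.csv``.

In memory the streams carry ``t_s`` — seconds since the participant's
follow-up start; the writers render calendar timestamps from each
participant's ``start_date`` and the readers invert the mapping, so a
write-read round trip reproduces the records.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import Cohort

STREAM_SCHEMAS: dict[str, list[str]] = {
    "participants": ["participant_id", "start_date", "weight_kg",
                     "resting_hr", "walk_speed_shift", "count_mult"],
    "timetable": ["participant_id", "start_minute", "end_minute", "mode"],
    "fixes": ["participant_id", "timestamp", "lat", "lon", "elevation",
              "speed", "hdop", "vdop", "pdop", "sat_in_view", "sat_used"],
    "epochs": ["participant_id", "timestamp", "filter_variant",
               "counts_axis1", "counts_axis2", "counts_axis3", "steps"],
    "rr": ["participant_id", "timestamp", "rr_ms"],
}


class SchemaError(ValueError):
    """Raised when a CSV is missing required columns or has bad rows."""


def _require_columns(df: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{name}: missing required column(s) {missing}; "
            f"found {list(df.columns)}")


def _parse_timestamps(series: pd.Series, name: str) -> pd.Series:
    """Parse ISO-8601 timestamps; timezone-aware values are converted to
    the cohort clock (naive UTC)."""
    try:
        ts = pd.to_datetime(series, format="ISO8601", utc=True)
    except (ValueError, TypeError) as exc:
        bad = pd.to_datetime(series, format="ISO8601",
                             errors="coerce", utc=True)
        lines = (np.flatnonzero(bad.isna().to_numpy()) + 2)[:5]
        raise SchemaError(
            f"{name}: malformed timestamp(s) near line(s) "
            f"{lines.tolist()}: {exc}") from exc
    return ts.dt.tz_localize(None)


def _starts(participants: pd.DataFrame) -> pd.Series:
    return pd.to_datetime(participants.set_index("participant_id")
                          ["start_date"])


def _write_stream(df: pd.DataFrame, starts: pd.Series, path: Path,
                  columns: list[str]) -> None:
    out = df.copy()
    base = out["participant_id"].map(starts)
    ts = pd.to_datetime(base) + pd.to_timedelta(
        np.round(out["t_s"].to_numpy() * 1e6).astype(np.int64), unit="us")
    out["timestamp"] = ts.dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
    out[columns].to_csv(path, index=False)


def _read_stream(path: Path, starts: pd.Series, name: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, STREAM_SCHEMAS[name], name)
    unknown = df.loc[~df["participant_id"].isin(starts.index),
                     "participant_id"].unique()
    if unknown.size:
        raise SchemaError(
            f"{name}: unknown participant id(s) {unknown[:5].tolist()}")
    ts = _parse_timestamps(df["timestamp"], name)
    base = df["participant_id"].map(starts)
    df["t_s"] = (ts - base).dt.total_seconds()
    return df.drop(columns=["timestamp"])


def write_cohort(cohort: Cohort, outdir) -> dict[str, Path]:
    """Write a cohort's five CSV files; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    starts = _starts(cohort.participants)

    paths = {}
    p = cohort.participants.copy()
    p["start_date"] = pd.to_datetime(p["start_date"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S")
    paths["participants"] = outdir / "participants.csv"
    p[STREAM_SCHEMAS["participants"]].to_csv(paths["participants"],
                                             index=False)

    paths["timetable"] = outdir / "timetable.csv"
    cohort.timetable[STREAM_SCHEMAS["timetable"]].to_csv(
        paths["timetable"], index=False)

    for name, df, fname in (("fixes", cohort.gps, "fixes.csv"),
                            ("epochs", cohort.accel, "epochs.csv"),
                            ("rr", cohort.rr, "rr.csv")):
        paths[name] = outdir / fname
        _write_stream(df, starts, paths[name], STREAM_SCHEMAS[name])
    return paths


def read_cohort_tables(indir) -> dict[str, pd.DataFrame]:
    """Read the five cohort CSVs back into in-memory stream frames.

    Returns a dict with keys participants, timetable, gps, accel, rr;
    the stream frames carry ``t_s`` seconds as produced by the
    simulator. Validates schemas and reports malformed rows.
    """
    indir = Path(indir)
    participants = pd.read_csv(indir / "participants.csv")
    _require_columns(participants, STREAM_SCHEMAS["participants"],
                     "participants")
    participants["start_date"] = _parse_timestamps(
        participants["start_date"], "participants")
    starts = _starts(participants)

    timetable = pd.read_csv(indir / "timetable.csv")
    _require_columns(timetable, STREAM_SCHEMAS["timetable"], "timetable")

    return {
        "participants": participants,
        "timetable": timetable,
        "gps": _read_stream(indir / "fixes.csv", starts, "fixes"),
        "accel": _read_stream(indir / "epochs.csv", starts, "epochs"),
        "rr": _read_stream(indir / "rr.csv", starts, "rr"),
    }


def write_minutes(minutes: pd.DataFrame, path) -> None:
    """Write the labelled minute-level dataset; missing values are empty
    fields. Column order: participant_id, minute, timestamp, label, then
    the catalogue order."""
    out = minutes.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False, na_rep="")


def read_minutes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["participant_id", "minute", "timestamp", "label"],
                     "minutes")
    df["timestamp"] = _parse_timestamps(df["timestamp"], "minutes")
    return df


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, config_dict: dict, seed: int,
                   stage_seeds: dict[str, int],
                   output_files: dict[str, str],
                   timings_s: dict[str, float]) -> None:
    """JSON run manifest: config snapshot, seeds, software versions,
    output hashes and timings — enough to reproduce a run byte for byte
    in the same environment."""
    import sklearn

    manifest = {
        "config": config_dict,
        "master_seed": seed,
        "stage_seeds": stage_seeds,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "output_sha256": output_files,
        "timings_s": {k: round(v, 3) for k, v in timings_s.items()},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
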