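"""Canonical tables for vocalization-detection pipelines.

Four tables flow through the pipeline, all plain CSV (RFC-4180):

* **detections** — one row per classifier output event: which species was
  claimed, at which recorder, when, and with what confidence score.
* **recorders** — one row per recorder deployment interval: coordinates,
  habitat class, dataset membership.
* **labels** — expert true/false-positive judgments on individual detections.
* **effort** — recorded hours per recorder per local calendar day.

All functions exchange :class:`pandas.DataFrame` objects with the column sets
documented below; a light dataclass (:class:`Recorder`) is provided for
programmatic construction of recorder tables.

Timestamps are stored as UTC plus an explicit local offset in minutes.  Diel
summaries need local solar time, and carrying the offset as data avoids any
timezone-database dependency: ``local = timestamp_utc + local_offset_minutes``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "DETECTION_COLUMNS",
    "RECORDER_COLUMNS",
    "LABEL_COLUMNS",
    "EFFORT_COLUMNS",
    "SchemaError",
    "ReferentialIntegrityError",
    "Recorder",
    "ReadResult",
    "read_detections",
    "write_detections",
    "read_recorders",
    "write_recorders",
    "recorders_frame",
    "read_labels",
    "write_labels",
    "read_effort",
    "write_effort",
    "join_metadata",
    "local_times",
    "make_detection_id",
]

#: Canonical detection-table columns, in writing order.
DETECTION_COLUMNS = [
    "detection_id",
    "dataset_id",
    "recorder_id",
    "species",
    "score",
    "timestamp_utc",
    "local_offset_minutes",
    "source_file",
    "start_offset_s",
    "end_offset_s",
]

RECORDER_COLUMNS = [
    "recorder_id",
    "dataset_id",
    "latitude",
    "longitude",
    "habitat",
    "deployment_start",
    "deployment_end",
]

LABEL_COLUMNS = ["detection_id", "label", "labeler_id"]

EFFORT_COLUMNS = ["recorder_id", "date", "recorded_hours"]

TRUE_POSITIVE = "true_positive"
FALSE_POSITIVE = "false_positive"

#: Column mapping for CSVs written by the BirdNET-Analyzer tool.
_BIRDNET_COLUMNS = {
    "Start (s)": "start_offset_s",
    "End (s)": "end_offset_s",
    "Common name": "species",
    "Confidence": "score",
}


class SchemaError(ValueError):
    """A required column is missing or a table's header does not match."""


class ReferentialIntegrityError(ValueError):
    """A foreign key (detection_id / recorder_id) does not resolve."""


@dataclass(frozen=True)
class Recorder:
    """One recorder deployment: location, habitat and active interval."""

    recorder_id: str
    dataset_id: str
    latitude: float
    longitude: float
    habitat: str
    deployment_start: str | pd.Timestamp | None = None
    deployment_end: str | pd.Timestamp | None = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")


class ReadResult(NamedTuple):
    """Accepted rows plus row-level diagnostics for rejected ones.

    ``detections`` holds the accepted rows in canonical form;
    ``rejected`` has one row per rejected input row with its (1-based,
    header-exclusive) ``line`` and a human-readable ``reason``.
    ``len(detections) + len(rejected)`` always equals the input row count.
    """

    detections: pd.DataFrame
    rejected: pd.DataFrame


def normalize_species(name: pd.Series | str) -> pd.Series | str:
    """Whitespace/case normalization used before any species-name match.

    Matching is exact after this normalization; no fuzzy matching is ever
    attempted (a misjoin is worse than a miss).
    """
    if isinstance(name, str):
        return " ".join(name.split()).lower()
    return name.str.split().str.join(" ").str.lower()


def make_detection_id(source_file, start_offset_s, species) -> pd.Series:
    """Deterministic detection id from (source_file, start_offset_s, species).

    Used whenever an input table carries no id of its own, so that label
    sheets join back to detections stably across re-reads.
    """
    frame = pd.DataFrame(
        {
            "f": pd.Series(source_file, dtype="string"),
            "s": pd.Series(start_offset_s, dtype="float64").map(lambda v: f"{v:.3f}"),
            "sp": pd.Series(species, dtype="string"),
        }
    )
    keys = frame["f"] + "|" + frame["s"] + "|" + frame["sp"]
    return keys.map(lambda k: hashlib.sha1(k.encode()).hexdigest()[:16])


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {', '.join(missing)}")


def _empty_detections() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype="object") for c in DETECTION_COLUMNS})
    df["score"] = df["score"].astype(float)
    df["timestamp_utc"] = pd.to_datetime(df["timestamp_utc"])
    df["local_offset_minutes"] = df["local_offset_minutes"].astype("int64")
    df["start_offset_s"] = df["start_offset_s"].astype(float)
    df["end_offset_s"] = df["end_offset_s"].astype(float)
    return df


def read_detections(
    path,
    dialect: str = "canonical",
    *,
    dataset_id: str | None = None,
    recorder_id: str | None = None,
    recording_start_utc: str | pd.Timestamp | None = None,
    local_offset_minutes: int = 0,
) -> ReadResult:
    """Read a detection CSV into canonical form, rejecting invalid rows.

    Parameters
    ----------
    path
        CSV file to read.
    dialect
        ``"canonical"`` for this package's own schema, or
        ``"birdnet_analyzer"`` for the result tables written by the
        BirdNET-Analyzer tool (columns ``Start (s)``, ``End (s)``,
        ``Scientific name``, ``Common name``, ``Confidence``).
    dataset_id, recorder_id, recording_start_utc, local_offset_minutes
        Fill-ins for fields the ``birdnet_analyzer`` dialect does not carry.
        ``recording_start_utc`` anchors absolute timestamps:
        ``timestamp_utc = recording_start_utc + start_offset_s``.

    Returns
    -------
    ReadResult
        Accepted detections plus a diagnostics frame for rejected rows.
        Rows violating invariants (score outside (0, 1], end <= start,
        unparseable score/timestamp, duplicate detection_id within a dataset)
        are rejected individually; a missing column raises :class:`SchemaError`.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if dialect == "birdnet_analyzer":
        raw = _birdnet_to_canonical(
            raw,
            dataset_id=dataset_id or "default",
            recorder_id=recorder_id or "default",
            recording_start_utc=recording_start_utc,
            local_offset_minutes=local_offset_minutes,
        )
    elif dialect != "canonical":
        raise ValueError(f"unknown dialect {dialect!r}")
    _require_columns(raw, DETECTION_COLUMNS, "detection table")
    if raw.empty:
        return ReadResult(_empty_detections(), pd.DataFrame(columns=["line", "reason"]))

    reasons = pd.Series("", index=raw.index, dtype="object")

    def flag(mask: pd.Series, reason: str) -> None:
        fresh = mask & (reasons == "")
        reasons[fresh] = reason

    score = pd.to_numeric(raw["score"], errors="coerce")
    flag(score.isna(), "unparseable score")
    flag(~score.isna() & ~((score > 0) & (score <= 1)), "score outside (0, 1]")

    ts = pd.to_datetime(raw["timestamp_utc"], errors="coerce", utc=False, format="ISO8601")
    flag(ts.isna(), "unparseable timestamp_utc")

    start = pd.to_numeric(raw["start_offset_s"], errors="coerce")
    end = pd.to_numeric(raw["end_offset_s"], errors="coerce")
    flag(start.isna() | end.isna(), "unparseable start/end offset")
    flag(~start.isna() & (start < 0), "negative start_offset_s")
    flag(~start.isna() & ~end.isna() & (end <= start), "end_offset_s <= start_offset_s")

    offset = pd.to_numeric(raw["local_offset_minutes"], errors="coerce")
    flag(offset.isna(), "unparseable local_offset_minutes")

    dup = raw.duplicated(subset=["dataset_id", "detection_id"], keep="first")
    flag(dup, "duplicate detection_id within dataset")

    bad = reasons != ""
    rejected = pd.DataFrame(
        {"line": (raw.index[bad] + 1).astype(int), "reason": reasons[bad].to_numpy()}
    ).reset_index(drop=True)

    ok = raw[~bad].copy()
    ok["score"] = score[~bad]
    ok["timestamp_utc"] = ts[~bad]
    ok["local_offset_minutes"] = offset[~bad].astype("int64")
    ok["start_offset_s"] = start[~bad]
    ok["end_offset_s"] = end[~bad]
    ok = ok[DETECTION_COLUMNS].reset_index(drop=True)
    return ReadResult(ok, rejected)


def _birdnet_to_canonical(
    raw: pd.DataFrame,
    *,
    dataset_id: str,
    recorder_id: str,
    recording_start_utc,
    local_offset_minutes: int,
) -> pd.DataFrame:
    _require_columns(raw, list(_BIRDNET_COLUMNS), "BirdNET-Analyzer table")
    out = raw.rename(columns=_BIRDNET_COLUMNS)[list(_BIRDNET_COLUMNS.values())].copy()
    out["dataset_id"] = raw.get("Dataset", dataset_id)
    out["recorder_id"] = raw.get("Recorder", recorder_id)
    out["source_file"] = raw.get("File", raw.get("Begin Path", ""))
    start_s = pd.to_numeric(out["start_offset_s"], errors="coerce")
    if "Timestamp" in raw.columns:
        out["timestamp_utc"] = raw["Timestamp"]
    else:
        base = pd.to_datetime(recording_start_utc) if recording_start_utc is not None else pd.Timestamp("1970-01-01")
        out["timestamp_utc"] = (base + pd.to_timedelta(start_s, unit="s")).dt.strftime(
            "%Y-%m-%dT%H:%M:%S"
        )
    out["local_offset_minutes"] = str(int(local_offset_minutes))
    out["detection_id"] = make_detection_id(out["source_file"], start_s, out["species"])
    return out[DETECTION_COLUMNS]


def write_detections(detections: pd.DataFrame, path) -> None:
    """Write detections in canonical CSV form.

    Scores are written with 6 decimal places and offsets with 3, so a
    write/read round trip reproduces every field to that stated precision.
    """
    _require_columns(detections, DETECTION_COLUMNS, "detection table")
    out = detections[DETECTION_COLUMNS].copy()
    out["score"] = out["score"].map(lambda v: f"{v:.6f}")
    out["timestamp_utc"] = pd.to_datetime(out["timestamp_utc"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S"
    )
    out["start_offset_s"] = out["start_offset_s"].map(lambda v: f"{v:.3f}")
    out["end_offset_s"] = out["end_offset_s"].map(lambda v: f"{v:.3f}")
    out.to_csv(path, index=False, lineterminator="\n")


def recorders_frame(recorders: Iterable[Recorder]) -> pd.DataFrame:
    """Build a canonical recorder table from :class:`Recorder` objects."""
    rows = [
        {
            "recorder_id": r.recorder_id,
            "dataset_id": r.dataset_id,
            "latitude": r.latitude,
            "longitude": r.longitude,
            "habitat": r.habitat,
            "deployment_start": r.deployment_start,
            "deployment_end": r.deployment_end,
        }
        for r in recorders
    ]
    return pd.DataFrame(rows, columns=RECORDER_COLUMNS)


def read_recorders(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, RECORDER_COLUMNS[:5], "recorder table")
    bad_lat = ~df["latitude"].between(-90, 90)
    bad_lon = ~df["longitude"].between(-180, 180)
    if bad_lat.any() or bad_lon.any():
        raise ValueError("recorder coordinates outside valid ranges")
    return df


def write_recorders(recorders: pd.DataFrame, path) -> None:
    recorders.to_csv(path, index=False, lineterminator="\n")


def read_labels(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ["detection_id", "label"], "label table")
    if "labeler_id" not in df.columns:
        df["labeler_id"] = "unknown"
    bad = ~df["label"].isin([TRUE_POSITIVE, FALSE_POSITIVE])
    if bad.any():
        raise ValueError(
            f"unknown label token(s) at line(s) {(df.index[bad] + 1).tolist()}"
        )
    if df.duplicated(subset=["detection_id", "labeler_id"]).any():
        raise ValueError("more than one label per detection per labeler")
    return df[LABEL_COLUMNS]


def write_labels(labels: pd.DataFrame, path) -> None:
    labels[LABEL_COLUMNS].to_csv(path, index=False, lineterminator="\n")


def read_effort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, EFFORT_COLUMNS, "effort table")
    if not df["recorded_hours"].between(0, 24).all():
        raise ValueError("recorded_hours outside [0, 24]")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return df


def write_effort(effort: pd.DataFrame, path) -> None:
    out = effort[EFFORT_COLUMNS].copy()
    out["recorded_hours"] = out["recorded_hours"].map(lambda v: f"{v:.3f}")
    out.to_csv(path, index=False, lineterminator="\n")


def local_times(detections: pd.DataFrame) -> pd.Series:
    """Local wall-clock timestamps: ``timestamp_utc + local_offset_minutes``."""
    return pd.to_datetime(detections["timestamp_utc"]) + pd.to_timedelta(
        detections["local_offset_minutes"], unit="m"
    )


def join_metadata(
    detections: pd.DataFrame, recorders: pd.DataFrame, strict: bool = True
) -> pd.DataFrame:
    """Attach recorder coordinates/habitat and local-time fields to detections.

    Adds ``latitude``, ``longitude``, ``habitat``, ``local_time``,
    ``local_hour`` (0-23), ``local_date`` and a ``recorder_known`` flag.
    Under ``strict=True`` an unknown recorder_id raises
    :class:`ReferentialIntegrityError` listing the offending ids; otherwise the
    rows are kept with ``recorder_known=False`` and missing metadata.
    """
    meta = recorders.drop_duplicates("recorder_id")[
        ["recorder_id", "latitude", "longitude", "habitat"]
    ]
    out = detections.merge(meta, on="recorder_id", how="left", indicator=True)
    known = out.pop("_merge") == "both"
    if strict and not known.all():
        unknown = sorted(out.loc[~known, "recorder_id"].unique())
        raise ReferentialIntegrityError(f"unknown recorder_id(s): {unknown}")
    out["recorder_known"] = known.to_numpy()
    local = local_times(out)
    out["local_time"] = local
    out["local_hour"] = local.dt.hour
    out["local_date"] = local.dt.date
    return out
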