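"""Expert-validation sampling: draw detections to label, manage label sheets.

The validation design follows the per-group budget convention: for each
(dataset, species) group a fixed number of detections (default 50) is drawn
uniformly at random without replacement from everything the classifier
exported (i.e. all detections at or above the export floor).  The sample is
written as a label sheet the expert fills with ``tp``/``fp`` tokens; ingesting
the sheet yields canonical validation labels.
"""

from __future__ import annotations

import zlib
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io import FALSE_POSITIVE, LABEL_COLUMNS, TRUE_POSITIVE

__all__ = ["sample_for_validation", "make_label_sheet", "ingest_labels", "IngestResult"]

SHEET_COLUMNS = [
    "detection_id",
    "dataset_id",
    "species",
    "source_file",
    "start_offset_s",
    "end_offset_s",
    "label",
]

_SHEET_TOKENS = {"tp": TRUE_POSITIVE, "fp": FALSE_POSITIVE}


def _group_rng(seed: int, dataset_id: str, species: str) -> np.random.Generator:
    # per-group sub-seeding keeps a group's draw invariant to which other
    # groups happen to be present in the table
    entropy = (seed, zlib.crc32(dataset_id.encode()), zlib.crc32(species.encode()))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def sample_for_validation(
    detections: pd.DataFrame, n_per_species: int = 50, seed: int = 0
) -> pd.DataFrame:
    """Uniform without-replacement sample per (dataset, species) group.

    Groups with fewer than ``n_per_species`` detections are taken whole.
    Reproducible under ``seed``; the rows returned keep all detection columns
    and are ordered by (dataset, species, detection_id).
    """
    if detections.empty:
        raise ValueError("cannot sample from an empty detection table")
    if n_per_species < 1:
        raise ValueError("n_per_species must be >= 1")
    picks = []
    for (dataset_id, species), group in detections.groupby(
        ["dataset_id", "species"], sort=True
    ):
        group = group.sort_values("detection_id", kind="mergesort")
        k = min(n_per_species, len(group))
        rng = _group_rng(seed, str(dataset_id), str(species))
        idx = rng.choice(len(group), size=k, replace=False)
        picks.append(group.iloc[np.sort(idx)])
    out = pd.concat(picks, ignore_index=True)
    return out.sort_values(
        ["dataset_id", "species", "detection_id"], kind="mergesort"
    ).reset_index(drop=True)


def make_label_sheet(sample: pd.DataFrame, path=None) -> pd.DataFrame:
    """Build (and optionally write) a label sheet for a validation sample.

    One row per sampled detection, species-contiguous (ordered by species then
    detection_id) to match per-species labeling sessions; the ``label`` column
    is blank and accepts the tokens ``tp`` / ``fp``.
    """
    if sample.empty:
        raise ValueError("cannot build a label sheet from an empty sample")
    sheet = sample.sort_values(
        ["species", "detection_id"], kind="mergesort"
    ).reset_index(drop=True)
    sheet = sheet[
        ["detection_id", "dataset_id", "species", "source_file", "start_offset_s", "end_offset_s"]
    ].copy()
    sheet["label"] = ""
    if path is not None:
        out = sheet.copy()
        out["start_offset_s"] = out["start_offset_s"].map(lambda v: f"{v:.3f}")
        out["end_offset_s"] = out["end_offset_s"].map(lambda v: f"{v:.3f}")
        out.to_csv(path, index=False, lineterminator="\n")
    return sheet


class IngestResult(NamedTuple):
    labels: pd.DataFrame  # canonical ValidationLabel rows
    unlabeled: pd.DataFrame  # sheet rows left blank, reported not errored


def ingest_labels(sheet, labeler_id: str = "expert") -> IngestResult:
    """Turn a filled label sheet into canonical validation labels.

    ``tp``/``fp`` tokens map to true_positive/false_positive; blank rows are
    reported as unlabeled; any other token raises naming the offending rows,
    as does a duplicated detection_id.
    """
    if not isinstance(sheet, pd.DataFrame):
        sheet = pd.read_csv(sheet, dtype=str, keep_default_na=False)
    if "label" not in sheet.columns:
        raise ValueError("label sheet has no 'label' column")
    tokens = sheet["label"].astype(str).str.strip().str.lower()
    blank = tokens == ""
    bad = ~blank & ~tokens.isin(_SHEET_TOKENS)
    if bad.any():
        rows = (sheet.index[bad] + 1).tolist()
        raise ValueError(f"unknown label token(s) {sorted(tokens[bad].unique())} at row(s) {rows}")
    if sheet["detection_id"].duplicated().any():
        dups = sorted(sheet.loc[sheet["detection_id"].duplicated(), "detection_id"])
        raise ValueError(f"conflicting duplicate detection_id(s): {dups}")
    labeled = sheet[~blank]
    labels = pd.DataFrame(
        {
            "detection_id": labeled["detection_id"].to_numpy(),
            "label": tokens[~blank].map(_SHEET_TOKENS).to_numpy(),
            "labeler_id": labeler_id,
        },
        columns=LABEL_COLUMNS,
    )
    return IngestResult(labels, sheet[blank].reset_index(drop=True))


def labels_from_truth(sample: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Restrict simulator ground-truth labels to a validation sample.

    Stands in for the human expert when running the pipeline on synthetic
    streams: the returned labels are exactly the truth rows for the sampled
    detection_ids.
    """
    keep = truth["detection_id"].isin(set(sample["detection_id"]))
    return truth[keep].reset_index(drop=True)
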