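"""Detection-reliability filters producing the trusted detection set.

Three stages, applied in the pipeline default order
allowlist -> minimum raw count -> calibrated thresholds:

1. an optional per-recorder species allow-list (detections of species not
   expected at a recorder's location are dropped);
2. a per-(species, dataset) minimum raw detection count (default: strictly
   more than 50), ensuring enough material to validate;
3. the calibrated classification thresholds: a detection survives iff its
   species is reliable in its dataset, the species retains strictly more
   than ``min_detections_post`` detections at its threshold, and the
   detection's own score is at or above the threshold.

Every filter returns the kept subset plus a drop report; each dropped
detection appears in exactly one report row with a reason code.
"""

from __future__ import annotations

from typing import Mapping, NamedTuple, Set

import pandas as pd

from .calibration import CalibrationResults

__all__ = [
    "FilterResult",
    "filter_min_raw_detections",
    "apply_calibrated_thresholds",
    "species_allowlist_filter",
    "apply_filters",
]

DROP_COLUMNS = ["detection_id", "dataset_id", "species", "reason"]


class FilterResult(NamedTuple):
    kept: pd.DataFrame
    dropped: pd.DataFrame  # DROP_COLUMNS
    report: pd.DataFrame  # per-group summary, stage specific


def _drops(detections: pd.DataFrame, mask, reason: str) -> pd.DataFrame:
    out = detections.loc[mask, ["detection_id", "dataset_id", "species"]].copy()
    out["reason"] = reason
    return out


def filter_min_raw_detections(
    detections: pd.DataFrame, min_count: int = 50
) -> FilterResult:
    """Keep species with strictly more than ``min_count`` raw detections.

    Counting is per (dataset, species): a species is evaluated independently
    in each dataset it appears in.  The report lists every group with its
    count and kept/dropped status.
    """
    counts = (
        detections.groupby(["dataset_id", "species"], sort=True)
        .size()
        .rename("n_detections")
        .reset_index()
    )
    counts["kept"] = counts["n_detections"] > min_count
    keep_keys = set(
        map(tuple, counts.loc[counts["kept"], ["dataset_id", "species"]].to_numpy())
    )
    key = list(zip(detections["dataset_id"], detections["species"]))
    mask = pd.Series([k in keep_keys for k in key], index=detections.index, dtype=bool)
    return FilterResult(
        detections[mask].reset_index(drop=True),
        _drops(detections, ~mask, "below_min_raw_detections").reset_index(drop=True),
        counts,
    )


def apply_calibrated_thresholds(
    detections: pd.DataFrame,
    calibration: CalibrationResults,
    permissive: bool = False,
) -> FilterResult:
    """Keep detections passing their species' calibrated threshold.

    A detection is kept iff its (species, dataset) calibration is reliable,
    meets the post-threshold minimum-count requirement, and the detection's
    score is at or above the chosen threshold (a score exactly at the
    threshold is kept).  A missing calibration raises unless ``permissive``,
    in which case those detections are dropped with a warning reason code.
    """
    reasons = pd.Series("", index=detections.index, dtype="object")
    for (dataset_id, species), group in detections.groupby(
        ["dataset_id", "species"], sort=False
    ):
        result = calibration.get(str(species), str(dataset_id))
        if result is None:
            if not permissive:
                raise KeyError(
                    f"no calibration for species {species!r} in dataset {dataset_id!r}"
                )
            reasons[group.index] = "missing_calibration"
        elif not result.reliable:
            reasons[group.index] = "unreliable_species"
        elif not result.meets_min_detections:
            reasons[group.index] = "too_few_surviving_detections"
        else:
            below = group.index[group["score"] < result.chosen_threshold]
            reasons[below] = "below_calibrated_threshold"
    mask = reasons == ""
    dropped = _drops(detections, ~mask, "")
    dropped["reason"] = reasons[~mask].to_numpy()
    report = (
        dropped.groupby(["dataset_id", "species", "reason"]).size().rename("n_dropped").reset_index()
    )
    return FilterResult(
        detections[mask].reset_index(drop=True),
        dropped.reset_index(drop=True),
        report,
    )


def species_allowlist_filter(
    detections: pd.DataFrame,
    allowlist: Mapping[str, Set[str]],
    permissive: bool = True,
) -> FilterResult:
    """Drop detections of species not expected at their recorder.

    ``allowlist`` maps recorder_id to the set of allowed species.  Recorders
    absent from the allowlist pass through unchanged under ``permissive``
    (the default — an empty allowlist is then the identity filter) and raise
    otherwise.
    """
    recorders = set(detections["recorder_id"].unique())
    uncovered = recorders - set(allowlist)
    if uncovered and not permissive:
        raise KeyError(f"allowlist does not cover recorder(s): {sorted(uncovered)}")
    ok = [
        rec not in allowlist or sp in allowlist[rec]
        for rec, sp in zip(detections["recorder_id"], detections["species"])
    ]
    mask = pd.Series(ok, index=detections.index, dtype=bool)
    dropped = _drops(detections, ~mask, "not_in_recorder_allowlist")
    report = (
        dropped.groupby(["dataset_id", "species"]).size().rename("n_dropped").reset_index()
    )
    return FilterResult(
        detections[mask].reset_index(drop=True),
        dropped.reset_index(drop=True),
        report,
    )


def apply_filters(
    detections: pd.DataFrame,
    calibration: CalibrationResults,
    allowlist: Mapping[str, Set[str]] | None = None,
    min_raw: int = 50,
    permissive: bool = False,
) -> FilterResult:
    """Default composition: allowlist -> min raw count -> calibrated thresholds.

    Returns the trusted detection set and the concatenated drop report; each
    input detection is either kept or appears exactly once with the reason
    from the first stage that dropped it.
    """
    stage1 = species_allowlist_filter(detections, allowlist or {}, permissive=True)
    stage2 = filter_min_raw_detections(stage1.kept, min_count=min_raw)
    stage3 = apply_calibrated_thresholds(stage2.kept, calibration, permissive=permissive)
    dropped = pd.concat(
        [stage1.dropped, stage2.dropped, stage3.dropped], ignore_index=True
    )[DROP_COLUMNS]
    return FilterResult(stage3.kept, dropped, stage3.report)
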