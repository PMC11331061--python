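"""Biodiversity summaries computed from the trusted detection set.

Four summaries, each a deterministic function of its inputs:

* **diel profiles** — detections per local hour of day, optionally effort
  corrected, normalized to a distribution over the 24 h;
* **habitat rates** — mean hourly vocalization rate per recorder-day,
  stratified by habitat, with the pooled 90th percentile stored as the
  display cap;
* **migration fronts** — per time bin, the median and interquartile range of
  the latitudes at which a species was detected, tracking range movement;
* **occurrence matrices** — species x time-bin counts or presence, with a
  species ordering from hierarchical clustering of presence rows
  (Jaccard distance, average linkage), the standard pairing for binary
  occurrence data.

Detections are expected in canonical form; latitude/habitat columns come
from :func:`birdcal.io.join_metadata`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io import local_times

__all__ = [
    "DielProfile",
    "HabitatRateSummary",
    "MigrationTrack",
    "OccurrenceMatrix",
    "diel_profile",
    "habitat_rates",
    "migration_front",
    "occurrence_matrix",
    "cluster_species_order",
    "circular_mean_hour",
]


@dataclass
class DielProfile:
    species: str
    counts: np.ndarray  # 24 values, local hours 0..23
    normalized: np.ndarray  # sums to 1 when any detections
    effort_corrected: bool
    empty: bool = False

    def peak_hour(self) -> float:
        """Circular mean hour of the profile (NaN for an empty profile)."""
        if self.empty:
            return float("nan")
        hours = np.arange(24) + 0.5  # bin centers
        return circular_mean_hour(hours, self.normalized)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.bar(np.arange(24), self.normalized, width=0.9)
        ax.set_xlabel("local hour")
        ax.set_ylabel("fraction of detections")
        ax.set_title(self.species)
        return ax


@dataclass
class HabitatRateSummary:
    species: str
    per_habitat: pd.DataFrame  # habitat, n_recorder_days, mean_daily_rate
    display_cap: float  # 90th percentile of pooled daily rates


@dataclass
class MigrationTrack:
    species: str
    bins: pd.DataFrame  # bin_start, n_detections, median_latitude, lat_q25, lat_q75
    slope_deg_per_week: float  # least-squares diagnostic over nonempty bins


@dataclass
class OccurrenceMatrix:
    values: pd.DataFrame  # species x bin-start columns
    mode: str  # "count" or "presence"
    bin_width_days: int
    row_order: list[int]  # permutation of range(n_species)

    @property
    def species(self) -> list[str]:
        return list(self.values.index)

    def ordered(self) -> pd.DataFrame:
        return self.values.iloc[self.row_order]


def circular_mean_hour(hours: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Weighted circular mean of hours on the 24 h circle, in [0, 24)."""
    theta = 2 * np.pi * np.asarray(hours, dtype=float) / 24.0
    w = np.ones_like(theta) if weights is None else np.asarray(weights, dtype=float)
    s, c = np.sum(w * np.sin(theta)), np.sum(w * np.cos(theta))
    return float((np.arctan2(s, c) % (2 * np.pi)) * 24.0 / (2 * np.pi))


def diel_profile(
    detections: pd.DataFrame,
    species: str,
    effort_by_hour: np.ndarray | None = None,
) -> DielProfile:
    """Distribution of a species' detections over the 24 local hours.

    ``effort_by_hour`` is an optional 24-vector of recorded hours per
    hour-of-day; when given, each hour's count is divided by its effort
    before normalization.  An absent species yields an empty, flagged
    profile rather than an error.
    """
    sub = detections[detections["species"] == species]
    if sub.empty:
        z = np.zeros(24)
        return DielProfile(species, z, z.copy(), effort_by_hour is not None, empty=True)
    if "local_hour" in sub.columns:
        hours = sub["local_hour"].to_numpy()
    else:
        hours = local_times(sub).dt.hour.to_numpy()
    counts = np.bincount(hours, minlength=24).astype(float)
    rates = counts.copy()
    if effort_by_hour is not None:
        effort = np.asarray(effort_by_hour, dtype=float)
        if effort.shape != (24,):
            raise ValueError("effort_by_hour must have 24 entries")
        with np.errstate(invalid="ignore", divide="ignore"):
            rates = np.where(effort > 0, counts / effort, 0.0)
    total = rates.sum()
    normalized = rates / total if total > 0 else rates
    return DielProfile(species, counts, normalized, effort_by_hour is not None)


def habitat_rates(
    detections: pd.DataFrame,
    species: str,
    recorders: pd.DataFrame,
    effort: pd.DataFrame,
) -> HabitatRateSummary:
    """Habitat-stratified mean hourly vocalization rates per recorder-day.

    The unit of observation is the recorder-day: rate = detections in that
    recorder's local day / recorded hours that day.  Recorder-days with
    effort but no detections contribute zero rates; a recorder-day with
    detections but no effort record is an error (no denominator).
    The display cap is the 90th percentile of the pooled daily rates.
    """
    sub = detections[detections["species"] == species].copy()
    if "local_date" not in sub.columns:
        sub["local_date"] = local_times(sub).dt.date
    day_counts = (
        sub.groupby(["recorder_id", "local_date"]).size().rename("n").reset_index()
    )
    frame = effort[effort["recorded_hours"] > 0].copy()
    merged = frame.merge(
        day_counts,
        left_on=["recorder_id", "date"],
        right_on=["recorder_id", "local_date"],
        how="outer",
        indicator=True,
    )
    orphan = merged["_merge"] == "right_only"
    if orphan.any():
        pairs = merged.loc[orphan, ["recorder_id", "local_date"]].to_records(index=False)
        raise ValueError(
            f"detections without an effort record for recorder-day(s): {list(pairs)[:5]}"
        )
    merged = merged[merged["_merge"] != "right_only"]
    merged["n"] = merged["n"].fillna(0.0)
    merged["daily_rate"] = merged["n"] / merged["recorded_hours"]
    hab = recorders.drop_duplicates("recorder_id")[["recorder_id", "habitat"]]
    merged = merged.merge(hab, on="recorder_id", how="left")
    per_habitat = (
        merged.groupby("habitat", sort=True)
        .agg(
            n_recorder_days=("daily_rate", "size"),
            mean_daily_rate=("daily_rate", "mean"),
        )
        .reset_index()
    )
    rates = merged["daily_rate"].to_numpy()
    cap = float(np.percentile(rates, 90)) if rates.size else 0.0
    return HabitatRateSummary(species, per_habitat, cap)


def _bin_starts(dates: pd.Series, bin_width_days: int) -> tuple[pd.Series, pd.DatetimeIndex]:
    d = pd.to_datetime(dates)
    origin = d.min().normalize()
    idx = ((d - origin).dt.days // bin_width_days).astype(int)
    span = int((d.max().normalize() - origin).days // bin_width_days)
    starts = origin + pd.to_timedelta(
        np.arange(span + 1) * bin_width_days, unit="D"
    )
    return idx, pd.DatetimeIndex(starts)


def migration_front(
    detections: pd.DataFrame, species: str, bin_width_days: int = 7
) -> MigrationTrack:
    """Time-binned latitude summaries tracking a species' range movement.

    Per nonempty bin: detection count, median latitude, 25th/75th percentile
    latitudes.  A least-squares slope of median latitude against time (in
    degrees/week) over the nonempty bins is attached as a diagnostic.
    """
    if bin_width_days < 1:
        raise ValueError("bin_width_days must be >= 1")
    sub = detections[detections["species"] == species].copy()
    if sub.empty:
        return MigrationTrack(species, pd.DataFrame(
            columns=["bin_start", "n_detections", "median_latitude", "lat_q25", "lat_q75"]
        ), float("nan"))
    if "local_date" not in sub.columns:
        sub["local_date"] = local_times(sub).dt.date
    idx, starts = _bin_starts(sub["local_date"], bin_width_days)
    sub["bin_start"] = starts[idx].to_numpy()
    bins = (
        sub.groupby("bin_start")["latitude"]
        .agg(
            n_detections="size",
            median_latitude="median",
            lat_q25=lambda v: float(np.percentile(v, 25)),
            lat_q75=lambda v: float(np.percentile(v, 75)),
        )
        .reset_index()
    )
    if len(bins) >= 2:
        weeks = (bins["bin_start"] - bins["bin_start"].iloc[0]).dt.days / 7.0
        slope = float(np.polyfit(weeks, bins["median_latitude"], 1)[0])
    else:
        slope = float("nan")
    return MigrationTrack(species, bins, slope)


def occurrence_matrix(
    detections: pd.DataFrame, bin_width_days: int = 7, mode: str = "count"
) -> OccurrenceMatrix:
    """Species x time-bin detection matrix over the detected date span.

    Bins are contiguous, equal width, labeled by start date, spanning first
    to last detection date.  ``presence`` mode thresholds counts at >= 1.
    The initial row order is alphabetical; see
    :func:`cluster_species_order` for the clustered ordering.
    """
    if bin_width_days < 1:
        raise ValueError("bin_width_days must be >= 1")
    if mode not in ("count", "presence"):
        raise ValueError(f"unknown mode {mode!r}")
    if detections.empty:
        raise ValueError("occurrence matrix needs at least one detection")
    sub = detections.copy()
    if "local_date" not in sub.columns:
        sub["local_date"] = local_times(sub).dt.date
    idx, starts = _bin_starts(sub["local_date"], bin_width_days)
    sub["bin_start"] = starts[idx].to_numpy()
    table = (
        sub.groupby(["species", "bin_start"]).size().unstack(fill_value=0)
    )
    table = table.reindex(columns=starts, fill_value=0)
    table = table.sort_index()
    if mode == "presence":
        table = (table >= 1).astype(int)
    return OccurrenceMatrix(
        values=table,
        mode=mode,
        bin_width_days=bin_width_days,
        row_order=list(range(len(table))),
    )


def cluster_species_order(matrix: OccurrenceMatrix) -> list[int]:
    """Species ordering from hierarchical clustering of presence rows.

    Agglomerative clustering with Jaccard distance and average linkage on
    the binarized rows; the returned permutation is the dendrogram leaf
    order.  Rows are processed in alphabetical species order, which makes
    the result invariant to the input row order and breaks ties
    deterministically by name.  A single species yields the identity order.
    """
    table = matrix.values.sort_index()
    alpha_to_input = [matrix.values.index.get_loc(s) for s in table.index]
    if len(table) < 2:
        return list(range(len(table)))
    presence = (table.to_numpy() >= 1).astype(bool)
    dist = pdist(presence, metric="jaccard")
    link = hierarchy.linkage(dist, method="average")
    leaves = hierarchy.leaves_list(link)
    return [alpha_to_input[i] for i in leaves]
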