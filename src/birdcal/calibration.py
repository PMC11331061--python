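"""Per-species classification-threshold calibration from labeled subsamples.

The estimand is precision, Tp/(Tp+Fp), of a species' detection stream when
only detections scoring at or above a threshold are kept.  Precision is
estimated on the expert-labeled subsample restricted to scores >= t for every
t on a fixed grid (default 0.80 to 0.99 inclusive, step 0.01), and the
calibrated threshold is the lowest grid value whose estimated precision
reaches the target (default 90%).

The modelling surface follows the model/results convention:

>>> model = ThresholdCalibration(detections, labels)
>>> res = model.fit()
>>> res.summary()          # one row per (species, dataset)
>>> res.curves()           # long-format precision curves
>>> res.get("sp", "ds")    # a single CalibrationResult

Because the labeling budget is fixed (one sample, labeled once), precision at
higher thresholds is computed on the surviving subset of that same sample;
grid points where fewer than ``min_labeled`` labeled detections survive are
flagged undefined and are never chosen.  Uncertainty is a 95% Wilson score
interval, which keeps sensible coverage at precision near 1 where much of the
mass sits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .io import FALSE_POSITIVE, TRUE_POSITIVE, ReferentialIntegrityError

__all__ = [
    "DEFAULT_GRID",
    "PrecisionEstimate",
    "CalibrationResult",
    "CalibrationResults",
    "ThresholdCalibration",
    "precision_at_threshold",
    "precision_curve",
    "select_threshold",
    "calibrate_all",
]

#: 0.80 .. 0.99 inclusive, step 0.01 — 20 grid points.
DEFAULT_GRID = tuple(np.round(np.arange(0.80, 0.995, 0.01), 2))


@dataclass(frozen=True)
class PrecisionEstimate:
    """Precision of the labeled subsample restricted to score >= threshold."""

    threshold: float
    tp: int
    fp: int
    precision: float  # NaN when undefined
    ci_low: float
    ci_high: float
    n_labeled_at_threshold: int
    defined: bool


@dataclass(frozen=True)
class CalibrationResult:
    """Calibration outcome for one (species, dataset) pair."""

    species: str
    dataset_id: str
    grid: tuple[float, ...]
    curve: tuple[PrecisionEstimate, ...]
    chosen_threshold: float | None
    reliable: bool
    detections_surviving: int
    meets_min_detections: bool

    @property
    def precision_at_chosen(self) -> float:
        if self.chosen_threshold is None:
            return float("nan")
        for est in self.curve:
            if est.threshold == self.chosen_threshold:
                return est.precision
        return float("nan")


def _wilson(tp: int, n: int, level: float) -> tuple[float, float]:
    lo, hi = proportion_confint(tp, n, alpha=1 - level, method="wilson")
    # pin degenerate counts to exact bounds so ci_low <= p_hat <= ci_high holds
    if tp == 0:
        lo = 0.0
    if tp == n:
        hi = 1.0
    return float(lo), float(hi)


def precision_at_threshold(
    labeled: pd.DataFrame,
    threshold: float,
    min_labeled: int = 5,
    ci_level: float = 0.95,
) -> PrecisionEstimate:
    """Precision estimate at one threshold from labeled detections.

    ``labeled`` needs ``score`` and ``label`` columns; counts are restricted
    to rows with score >= threshold.  With fewer than ``min_labeled``
    surviving labels the estimate is flagged undefined (NaN precision) —
    such grid points are ineligible for threshold selection.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    at = labeled[labeled["score"] >= threshold]
    tp = int((at["label"] == TRUE_POSITIVE).sum())
    fp = int((at["label"] == FALSE_POSITIVE).sum())
    n = tp + fp
    if n < max(min_labeled, 1):
        return PrecisionEstimate(threshold, tp, fp, float("nan"), float("nan"), float("nan"), n, False)
    lo, hi = _wilson(tp, n, ci_level)
    return PrecisionEstimate(threshold, tp, fp, tp / n, lo, hi, n, True)


def precision_curve(
    labeled: pd.DataFrame,
    grid: Sequence[float] = DEFAULT_GRID,
    min_labeled: int = 5,
    ci_level: float = 0.95,
) -> list[PrecisionEstimate]:
    """Precision estimates across the whole threshold grid."""
    grid = list(grid)
    if not grid:
        raise ValueError("threshold grid is empty")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("threshold grid must be strictly increasing")
    return [precision_at_threshold(labeled, t, min_labeled, ci_level) for t in grid]


def select_threshold(
    curve: Sequence[PrecisionEstimate], target: float = 0.90
) -> float | None:
    """Lowest grid threshold with defined precision >= target, else None."""
    if not 0.0 < target <= 1.0:
        raise ValueError(f"target {target} outside (0, 1]")
    for est in curve:
        if est.defined and est.precision >= target:
            return est.threshold
    return None


class ThresholdCalibration:
    """Calibration model over a detection table and its validation labels.

    Parameters
    ----------
    detections
        Full canonical detection table (used for surviving-detection counts).
    labels
        Validation labels; every ``detection_id`` must resolve to a detection.
    grid, target, min_labeled, min_detections_post, ci_level
        Grid of candidate thresholds; precision target; minimum surviving
        labels for a grid point to be eligible; minimum detections a species
        must retain after thresholding (strictly more than) to be usable
        downstream; Wilson interval level.
    """

    def __init__(
        self,
        detections: pd.DataFrame,
        labels: pd.DataFrame,
        grid: Sequence[float] = DEFAULT_GRID,
        target: float = 0.90,
        min_labeled: int = 5,
        min_detections_post: int = 20,
        ci_level: float = 0.95,
    ) -> None:
        self.detections = detections
        self.labels = labels
        self.grid = tuple(grid)
        self.target = target
        self.min_labeled = min_labeled
        self.min_detections_post = min_detections_post
        self.ci_level = ci_level

    @classmethod
    def from_csv(cls, detections_path, labels_path, **kwargs) -> "ThresholdCalibration":
        from . import io

        det, _ = io.read_detections(detections_path)
        return cls(det, io.read_labels(labels_path), **kwargs)

    def fit(self) -> "CalibrationResults":
        unknown = set(self.labels["detection_id"]) - set(self.detections["detection_id"])
        if unknown:
            raise ReferentialIntegrityError(
                f"labels reference unknown detection_id(s): {sorted(unknown)[:5]}"
            )
        joined = self.labels.merge(
            self.detections[["detection_id", "dataset_id", "species", "score"]],
            on="detection_id",
        )
        results = []
        for (dataset_id, species), group in joined.groupby(
            ["dataset_id", "species"], sort=True
        ):
            curve = precision_curve(group, self.grid, self.min_labeled, self.ci_level)
            chosen = select_threshold(curve, self.target)
            in_group = (self.detections["dataset_id"] == dataset_id) & (
                self.detections["species"] == species
            )
            surviving = (
                int((self.detections.loc[in_group, "score"] >= chosen).sum())
                if chosen is not None
                else 0
            )
            results.append(
                CalibrationResult(
                    species=str(species),
                    dataset_id=str(dataset_id),
                    grid=self.grid,
                    curve=tuple(curve),
                    chosen_threshold=chosen,
                    reliable=chosen is not None,
                    detections_surviving=surviving,
                    meets_min_detections=surviving > self.min_detections_post,
                )
            )
        return CalibrationResults(self, results)


class CalibrationResults:
    """Fitted calibration results: per-(species, dataset) thresholds and curves."""

    def __init__(self, model: ThresholdCalibration, results: list[CalibrationResult]):
        self.model = model
        self.results = results
        self._by_key = {(r.species, r.dataset_id): r for r in results}

    def __iter__(self):
        return iter(self.results)

    def __len__(self) -> int:
        return len(self.results)

    def get(self, species: str, dataset_id: str) -> CalibrationResult | None:
        return self._by_key.get((species, dataset_id))

    def summary(self) -> pd.DataFrame:
        """One row per (species, dataset): chosen threshold, precision, CI, status."""
        rows = []
        for r in self.results:
            est = next(
                (e for e in r.curve if e.threshold == r.chosen_threshold), None
            )
            rows.append(
                {
                    "dataset_id": r.dataset_id,
                    "species": r.species,
                    "chosen_threshold": r.chosen_threshold,
                    "precision": est.precision if est else float("nan"),
                    "ci_low": est.ci_low if est else float("nan"),
                    "ci_high": est.ci_high if est else float("nan"),
                    "n_labeled_at_threshold": est.n_labeled_at_threshold if est else 0,
                    "reliable": r.reliable,
                    "detections_surviving": r.detections_surviving,
                    "meets_min_detections": r.meets_min_detections,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "dataset_id",
                "species",
                "chosen_threshold",
                "precision",
                "ci_low",
                "ci_high",
                "n_labeled_at_threshold",
                "reliable",
                "detections_surviving",
                "meets_min_detections",
            ],
        )

    def curves(self) -> pd.DataFrame:
        """Long-format precision curves (one row per species x grid point)."""
        rows = [
            {
                "dataset_id": r.dataset_id,
                "species": r.species,
                "threshold": e.threshold,
                "tp": e.tp,
                "fp": e.fp,
                "n_labeled_at_threshold": e.n_labeled_at_threshold,
                "precision": e.precision,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "defined": e.defined,
            }
            for r in self.results
            for e in r.curve
        ]
        return pd.DataFrame(rows)

    def plot_curve(self, species: str, dataset_id: str, ax=None):
        """Precision-vs-threshold plot with Wilson band for one species."""
        import matplotlib.pyplot as plt

        r = self.get(species, dataset_id)
        if r is None:
            raise KeyError(f"no calibration for ({species!r}, {dataset_id!r})")
        if ax is None:
            _, ax = plt.subplots()
        t = [e.threshold for e in r.curve if e.defined]
        p = [e.precision for e in r.curve if e.defined]
        lo = [e.ci_low for e in r.curve if e.defined]
        hi = [e.ci_high for e in r.curve if e.defined]
        ax.fill_between(t, lo, hi, alpha=0.25, label="95% Wilson")
        ax.plot(t, p, marker="o", label="precision")
        ax.axhline(self.model.target, ls="--", color="grey")
        if r.chosen_threshold is not None:
            ax.axvline(r.chosen_threshold, ls=":", color="k")
        ax.set_xlabel("classification threshold")
        ax.set_ylabel("precision")
        ax.set_title(f"{species} ({dataset_id})")
        ax.legend()
        return ax


def calibrate_all(
    detections: pd.DataFrame,
    labels: pd.DataFrame,
    grid: Sequence[float] = DEFAULT_GRID,
    target: float = 0.90,
    min_labeled: int = 5,
    min_detections_post: int = 20,
    ci_level: float = 0.95,
) -> CalibrationResults:
    """Functional wrapper: build and fit a :class:`ThresholdCalibration`."""
    return ThresholdCalibration(
        detections, labels, grid, target, min_labeled, min_detections_post, ci_level
    ).fit()
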