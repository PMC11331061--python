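"""Precision estimation and threshold selection against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from birdcal import sampling
from birdcal.calibration import (
    DEFAULT_GRID,
    PrecisionEstimate,
    ThresholdCalibration,
    calibrate_all,
    precision_at_threshold,
    precision_curve,
    select_threshold,
)
from birdcal.io import ReferentialIntegrityError
from birdcal.simulate import analytic_precision
from tests.conftest import detection_frame, labeled_frame


def wilson_oracle(tp, n, z=1.959963984540054):
    """Independent hand-written Wilson score interval."""
    p = tp / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return center - half, center + half


def brute_force_select(thresholds, precisions, target):
    """Exhaustive scan oracle for threshold selection (NaN = undefined)."""
    for t, p in zip(thresholds, precisions):
        if not np.isnan(p) and p >= target:
            return t
    return None


class TestPrecisionAtThreshold:
    def test_forty_five_of_fifty(self):
        labeled = labeled_frame([0.9] * 50, ["tp"] * 45 + ["fp"] * 5)
        est = precision_at_threshold(labeled, 0.85)
        assert (est.tp, est.fp, est.precision) == (45, 5, 0.9)

    def test_hand_counted_restriction(self):
        labeled = labeled_frame([0.81, 0.85, 0.92, 0.95], ["tp", "fp", "tp", "tp"])
        est = precision_at_threshold(labeled, 0.90, min_labeled=1)
        assert (est.tp, est.fp, est.precision) == (2, 0, 1.0)

    def test_wilson_interval_matches_independent_formula(self):
        labeled = labeled_frame([0.9] * 50, ["tp"] * 45 + ["fp"] * 5)
        est = precision_at_threshold(labeled, 0.85)
        lo, hi = wilson_oracle(45, 50)
        assert np.isclose(est.ci_low, lo, atol=1e-9)
        assert np.isclose(est.ci_high, hi, atol=1e-9)
        assert (round(lo, 3), round(hi, 3)) == (0.786, 0.957)

    @pytest.mark.parametrize("tp,n", [(0, 10), (10, 10), (1, 7), (49, 50)])
    def test_wilson_random_cases(self, tp, n):
        labeled = labeled_frame([0.9] * n, ["tp"] * tp + ["fp"] * (n - tp))
        est = precision_at_threshold(labeled, 0.85, min_labeled=1)
        lo, hi = wilson_oracle(tp, n)
        assert np.isclose(est.ci_low, lo) and np.isclose(est.ci_high, hi)
        assert est.ci_low <= est.precision <= est.ci_high

    def test_below_min_labeled_is_undefined(self):
        labeled = labeled_frame([0.99, 0.99], ["tp", "tp"])
        est = precision_at_threshold(labeled, 0.9, min_labeled=5)
        assert not est.defined and np.isnan(est.precision)

    def test_threshold_domain_error(self):
        with pytest.raises(ValueError):
            precision_at_threshold(labeled_frame([0.9], ["tp"]), 1.5)


class TestPrecisionCurve:
    def test_default_grid_has_twenty_points(self):
        labeled = labeled_frame([0.9] * 50, ["tp"] * 50)
        curve = precision_curve(labeled)
        assert len(curve) == 20
        assert curve[0].threshold == 0.80 and curve[-1].threshold == 0.99

    def test_all_tp_gives_unit_precision_where_defined(self):
        labeled = labeled_frame(np.linspace(0.8, 1.0, 60), ["tp"] * 60)
        for est in precision_curve(labeled):
            if est.defined:
                assert est.precision == 1.0

    def test_labeled_count_non_increasing_in_threshold(self):
        rng = np.random.default_rng(5)
        labeled = labeled_frame(
            rng.uniform(0.8, 1.0, 200), rng.choice(["tp", "fp"], 200)
        )
        ns = [e.n_labeled_at_threshold for e in precision_curve(labeled, min_labeled=1)]
        assert all(b <= a for a, b in zip(ns, ns[1:]))

    def test_empty_or_unsorted_grid_rejected(self):
        labeled = labeled_frame([0.9], ["tp"])
        with pytest.raises(ValueError):
            precision_curve(labeled, grid=[])
        with pytest.raises(ValueError):
            precision_curve(labeled, grid=[0.9, 0.85])

    def test_ladder_curve_tracks_analytic_oracle(self, ladder_stream):
        cfg, det, truth = ladder_stream
        sample = sampling.sample_for_validation(det, 500, seed=11)
        labels = sampling.labels_from_truth(sample, truth)
        labeled = labels.merge(det[["detection_id", "species", "score"]], on="detection_id")
        cells = ok = 0
        for profile in cfg.species_profiles:
            group = labeled[labeled["species"] == profile.species]
            for est in precision_curve(group):
                if not est.defined:
                    continue
                p = analytic_precision(profile, est.threshold)
                sd = np.sqrt(p * (1 - p) / est.n_labeled_at_threshold)
                cells += 1
                ok += abs(est.precision - p) <= 3 * sd + 1e-12
        assert cells > 100
        assert ok / cells >= 0.95


class TestSelectThreshold:
    def test_stated_example(self):
        grid = [0.80, 0.81, 0.82, 0.83]
        precisions = [0.85, 0.88, 0.91, 0.95]
        curve = [
            PrecisionEstimate(t, 0, 0, p, p, p, 50, True)
            for t, p in zip(grid, precisions)
        ]
        assert select_threshold(curve, 0.90) == brute_force_select(grid, precisions, 0.90) == 0.82

    def test_qualifies_at_floor_and_never_qualifies(self):
        mk = lambda ps: [
            PrecisionEstimate(t, 0, 0, p, p, p, 50, not np.isnan(p))
            for t, p in zip([0.80, 0.81, 0.82], ps)
        ]
        assert select_threshold(mk([0.95, 0.96, 0.97])) == 0.80
        assert select_threshold(mk([0.5, 0.6, 0.7])) is None

    def test_undefined_points_never_chosen(self):
        curve = [
            PrecisionEstimate(0.80, 0, 0, np.nan, np.nan, np.nan, 2, False),
            PrecisionEstimate(0.81, 9, 1, 0.9, 0.6, 0.98, 10, True),
        ]
        assert select_threshold(curve) == 0.81

    def test_matches_brute_force_scan_on_random_curves(self):
        rng = np.random.default_rng(123)
        grid = list(DEFAULT_GRID)
        for _ in range(1000):
            precisions = rng.uniform(0.5, 1.0, len(grid))
            undefined = rng.random(len(grid)) < 0.2
            precisions[undefined] = np.nan
            target = rng.uniform(0.7, 0.99)
            curve = [
                PrecisionEstimate(t, 0, 0, p, p, p, 50, not np.isnan(p))
                for t, p in zip(grid, precisions)
            ]
            assert select_threshold(curve, target) == brute_force_select(
                grid, precisions, target
            )

    def test_target_domain_error(self):
        with pytest.raises(ValueError):
            select_threshold([], target=0.0)


class TestThresholdCalibrationModel:
    def test_species_in_two_datasets_gets_two_results(self):
        det = detection_frame(
            [
                {"detection_id": f"a{i}", "dataset_id": "ds1", "score": 0.95}
                for i in range(30)
            ]
            + [
                {"detection_id": f"b{i}", "dataset_id": "ds2", "score": 0.95}
                for i in range(30)
            ]
        )
        labels = pd.DataFrame(
            {
                "detection_id": [f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)],
                "label": ["true_positive"] * 10 + ["false_positive"] * 10,
                "labeler_id": "e",
            }
        )
        res = calibrate_all(det, labels)
        assert len(res) == 2
        assert res.get("species a", "ds1").reliable
        assert not res.get("species a", "ds2").reliable

    @pytest.mark.parametrize("n_det,expected", [(21, True), (20, False)])
    def test_min_detections_post_is_strict(self, n_det, expected):
        det = detection_frame(
            [{"detection_id": f"d{i}", "score": 0.95} for i in range(n_det)]
        )
        labels = pd.DataFrame(
            {
                "detection_id": [f"d{i}" for i in range(10)],
                "label": ["true_positive"] * 10,
                "labeler_id": "e",
            }
        )
        res = calibrate_all(det, labels)
        r = res.get("species a", "ds1")
        assert r.detections_surviving == n_det
        assert r.meets_min_detections is expected

    def test_unknown_label_reference_raises(self):
        det = detection_frame([{}])
        labels = pd.DataFrame(
            {"detection_id": ["ghost"], "label": ["true_positive"], "labeler_id": "e"}
        )
        with pytest.raises(ReferentialIntegrityError, match="ghost"):
            calibrate_all(det, labels)

    def test_summary_and_curves_shapes(self, ladder_stream):
        _, det, truth = ladder_stream
        sample = sampling.sample_for_validation(det, 50, seed=2)
        labels = sampling.labels_from_truth(sample, truth)
        res = ThresholdCalibration(det, labels).fit()
        summary = res.summary()
        assert len(summary) == 8
        assert set(summary.loc[summary["reliable"], "species"]) >= {"ladder_095", "ladder_100"}
        curves = res.curves()
        assert len(curves) == 8 * 20
        # reported precision at chosen threshold sits inside its Wilson interval
        chosen = summary.dropna(subset=["chosen_threshold"])
        assert ((chosen["ci_low"] <= chosen["precision"]) & (chosen["precision"] <= chosen["ci_high"])).all()


class TestParameterRecovery:
    """Chosen thresholds recover the analytic optimum across replicates."""

    def test_recovery_at_large_and_paper_scale_label_budgets(self, ladder_stream):
        from birdcal.simulate import analytic_optimal_threshold, scenario_preset, simulate_detections

        cfg, det, truth = ladder_stream
        optima = {
            p.species: analytic_optimal_threshold(p) for p in cfg.species_profiles
        }
        n_rep = 20
        exact_500 = within_50 = total = 0
        for seed in range(n_rep):
            for budget, counter in ((500, "exact"), (50, "near")):
                sample = sampling.sample_for_validation(det, budget, seed=seed)
                labels = sampling.labels_from_truth(sample, truth)
                res = ThresholdCalibration(det, labels).fit()
                for sp, true_opt in optima.items():
                    chosen = res.get(sp, cfg.dataset_id).chosen_threshold
                    if budget == 500:
                        exact_500 += (chosen == true_opt) or (
                            chosen is None and true_opt is None
                        )
                    else:
                        if chosen is None or true_opt is None:
                            within_50 += chosen is None and true_opt is None
                        else:
                            within_50 += abs(chosen - true_opt) <= 0.0100001
            total += len(optima)
        assert exact_500 / total >= 0.95
        assert within_50 / total >= 0.80
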