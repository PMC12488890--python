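import itertools
import math

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

import oracles
from twinforecast.evaluation import (
    MetricConfig,
    PatientSeries,
    auc_reference,
    auc_trend,
    correlation_preservation,
    evaluate_forecasts,
    forecast_errors,
    ks_statistic,
    label_reference,
    mann_whitney_auc,
    spearman_weighted,
    trend_labels,
    trend_score,
)

from conftest import make_example


def random_panel(rng, n_patients=None, max_points=8):
    """Small random panel of truth/pred series with occasional ties."""
    n = n_patients or int(rng.integers(1, 11))
    panel = []
    for _ in range(n):
        t_i = int(rng.integers(1, max_points + 1))
        offs = sorted(rng.choice(np.arange(1, max_points + 1), size=t_i, replace=False))
        truth = {int(o): float(np.round(rng.uniform(5, 15), 1)) for o in offs}
        pred = {int(o): float(np.round(rng.uniform(5, 15), 1)) for o in offs}
        v0 = float(np.round(rng.uniform(5, 15), 1)) if rng.random() < 0.8 else None
        panel.append(PatientSeries(truth=truth, pred=pred, v0=v0))
    return panel


def _dicts(panel):
    return ([s.truth for s in panel], [s.pred for s in panel], [s.v0 for s in panel])


# ---------------------------------------------------------------------------
# Regression metrics
# ---------------------------------------------------------------------------


class TestForecastErrors:
    def test_worked_single_patient_panel(self):
        panel = [PatientSeries(truth={1: 10.0, 2: 20.0}, pred={1: 12.0, 2: 16.0}, v0=10.0)]
        m = forecast_errors(panel, sigma=5.0)
        assert m["mae"] == pytest.approx(3.0)
        assert m["scaled_mae"] == pytest.approx(0.6)
        assert m["mase"] == pytest.approx(0.6)
        assert m["smape"] == pytest.approx(200 * (2 / 22 + 4 / 36) / 2)

    def test_patient_nesting_not_pooled(self):
        panel = [
            PatientSeries(truth={1: 10.0}, pred={1: 14.0}, v0=1.0),          # errs {4}
            PatientSeries(truth={1: 5.0, 2: 8.0}, pred={1: 6.0, 2: 5.0}, v0=1.0),  # {1,3}
        ]
        m = forecast_errors(panel, sigma=1.0)
        assert m["mae"] == pytest.approx(3.0)  # (4 + 2) / 2, not 8/3

    def test_perfect_forecast_zeroes_all_errors(self, rng):
        panel = random_panel(rng)
        for s in panel:
            s.pred = dict(s.truth)
        m = forecast_errors(panel, sigma=2.0)
        assert m["mae"] == 0 and m["scaled_mae"] == 0 and m["smape"] == 0
        if m["mase"] is not None:
            assert m["mase"] == 0

    def test_baseline_predictor_has_unit_mase(self, rng):
        panel = random_panel(rng, n_patients=8)
        for s in panel:
            if s.v0 is None:
                s.v0 = 9.0
            s.pred = {o: s.v0 for o in s.truth}
        m = forecast_errors(panel, sigma=1.0)
        if m["mase"] is not None:
            assert m["mase"] == pytest.approx(1.0)

    def test_scaled_mae_is_mae_over_sigma_bitwise(self, rng):
        for _ in range(20):
            panel = random_panel(rng)
            sigma = float(rng.uniform(0.5, 5))
            m = forecast_errors(panel, sigma)
            assert m["scaled_mae"] == m["mae"] / sigma

    def test_smape_bounded_and_zero_only_when_exact(self, rng):
        for _ in range(50):
            panel = random_panel(rng)
            m = forecast_errors(panel, sigma=1.0)
            assert 0 <= m["smape"] <= 200
            exact = all(s.truth[o] == s.pred[o] for s in panel for o in s.scored_offsets())
            assert (m["smape"] == 0) == exact

    def test_empty_panel_diagnostic(self):
        m = forecast_errors([PatientSeries(truth={}, pred={})], sigma=1.0)
        assert m["n_patients"] == 0 and m["mae"] is None and "diagnostic" in m

    def test_missing_v0_excluded_with_count(self):
        panel = [
            PatientSeries(truth={1: 10.0}, pred={1: 11.0}, v0=None),
            PatientSeries(truth={1: 10.0}, pred={1: 12.0}, v0=8.0),
        ]
        m = forecast_errors(panel, sigma=1.0)
        assert m["n_mase_excluded"] == 1
        assert m["mase"] == pytest.approx(2.0 / 2.0)


class TestSpearmanWeighted:
    def test_perfect_agreement(self, rng):
        panel = random_panel(rng)
        for s in panel:
            s.pred = dict(s.truth)
        assert spearman_weighted(panel) == pytest.approx(1.0)

    def test_antisymmetry_with_unit_counts(self):
        panel = [PatientSeries(truth={1: float(v)}, pred={1: float(-v)})
                 for v in (3, 1, 4, 5, 9, 2)]
        assert spearman_weighted(panel) == pytest.approx(-1.0)

    def test_zero_rank_variance_reported_missing(self):
        panel = [PatientSeries(truth={1: 5.0}, pred={1: 7.0}),
                 PatientSeries(truth={1: 5.0}, pred={1: 9.0})]
        assert spearman_weighted(panel) is None


# ---------------------------------------------------------------------------
# Reference-range classification
# ---------------------------------------------------------------------------


class TestLabelReference:
    def test_paper_style_male_hemoglobin(self):
        assert label_reference([13.0], (14.0, 18.0)) == ["low"]

    def test_boundary_equality_is_normal(self):
        assert label_reference([14.0, 18.0], (14.0, 18.0)) == ["normal", "normal"]

    def test_matches_brute_force_on_random_values(self, rng):
        values = rng.uniform(0, 30, size=500)
        got = label_reference(values, (10.0, 20.0))
        assert got == [oracles.label_value(v, 10.0, 20.0) for v in values]


class TestAucReference:
    def test_two_point_separation(self):
        out = auc_reference([4.0, 6.0], ["low", "normal"], (4.5, 20.0))
        assert out["auc_low"] == 1.0

    def test_two_point_swapped(self):
        out = auc_reference([6.0, 4.0], ["low", "normal"], (4.5, 20.0))
        assert out["auc_low"] == 0.0

    def test_all_tied_scores_give_half(self):
        out = auc_reference([5.0] * 6, ["low", "normal", "high"] * 2, (4.0, 6.0))
        for key in ("auc_low", "auc_normal", "auc_high", "auc_weighted"):
            assert out[key] == 0.5

    def test_weighted_aggregation_arithmetic(self):
        # per-class AUCs (1.0, 0.5, 1.0) with equal counts -> 5/6
        preds = [3.0, 5.0, 5.0, 9.0]
        labels = ["low", "normal", "normal", "high"]
        out = auc_reference(preds, labels, (4.0, 8.0))
        assert out["auc_low"] == 1.0 and out["auc_high"] == 1.0
        assert out["auc_weighted"] == pytest.approx(
            oracles.weighted_auc(
                {"low": out["auc_low"], "normal": out["auc_normal"], "high": out["auc_high"]},
                out["counts"]))

    def test_single_class_reported_missing(self):
        out = auc_reference([5.0, 6.0], ["normal", "normal"], (4.0, 8.0))
        assert out["auc_low"] is None and out["auc_high"] is None

    def test_mann_whitney_matches_sklearn_and_brute_force(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 20))
            scores = np.round(rng.uniform(0, 5, size=n), 1)
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            ours = mann_whitney_auc(scores, labels)
            assert ours == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)
            assert ours == pytest.approx(
                oracles.pairwise_auc(list(scores), list(labels)), abs=1e-12)


# ---------------------------------------------------------------------------
# Trends
# ---------------------------------------------------------------------------


class TestTrendLabels:
    def test_constant_trajectory_has_no_trend(self):
        traj = {t: 5.0 for t in range(5)}
        labels = trend_labels(traj, s=2)
        assert all(lab in ("neither", "excluded") for lab in labels.values())

    def test_worked_example(self):
        traj = {0: 5.0, 1: 4.0, 2: 3.0, 3: 3.0}
        labels = trend_labels(traj, s=2)
        assert labels == {0: "excluded", 1: "excluded", 2: "decreasing", 3: "neither"}

    def test_incomplete_window_excluded(self):
        traj = {0: 5.0, 2: 3.0, 3: 2.0}  # offset 1 missing
        labels = trend_labels(traj, s=2)
        assert labels[2] == "excluded" and labels[3] == "excluded"

    def test_enumeration_matches_brute_force(self):
        grid = (0.0, 1.0, 2.0)
        for length in range(1, 6):
            for values in itertools.product(grid, repeat=length):
                traj = dict(enumerate(values))
                for s in (1, 2, 3):
                    labels = trend_labels(traj, s)
                    for t in traj:
                        assert labels[t] == oracles.trend_label_brute(traj, t, s), (
                            values, s, t)


class TestAucTrend:
    def test_perfect_predictions_separate_fully(self):
        trajs = [
            {0: 5.0, 1: 4.0, 2: 3.0},
            {0: 1.0, 1: 2.0, 2: 3.0},
            {0: 2.0, 1: 1.0, 2: 4.0},
        ]
        out = auc_trend(trajs, trajs, s=2)
        assert out["auc_trend_up"] == 1.0 and out["auc_trend_down"] == 1.0

    def test_constant_predictions_score_half(self):
        truth = [{0: 5.0, 1: 4.0, 2: 3.0}, {0: 1.0, 1: 2.0, 2: 3.0}]
        pred = [{0: 2.0, 1: 2.0, 2: 2.0}, {0: 2.0, 1: 2.0, 2: 2.0}]
        out = auc_trend(pred, truth, s=2)
        assert out["auc_trend_up"] == 0.5 and out["auc_trend_down"] == 0.5

    def test_score_sign_is_consistent_with_label(self, rng):
        for _ in range(100):
            traj = {t: float(np.round(rng.uniform(0, 3), 1)) for t in range(4)}
            s = int(rng.integers(1, 3))
            labels = trend_labels(traj, s)
            for t, lab in labels.items():
                if lab == "excluded":
                    continue
                down = trend_score(traj, t, s, "decreasing")
                up = trend_score(traj, t, s, "increasing")
                assert (down > 0) == (lab == "decreasing")
                assert (up > 0) == (lab == "increasing")

    def test_matches_brute_force_mann_whitney(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 10))
            truth = [{t: float(np.round(rng.uniform(0, 3), 1)) for t in range(4)}
                     for _ in range(n)]
            pred = [{t: float(np.round(rng.uniform(0, 3), 1)) for t in range(4)}
                    for _ in range(n)]
            out = auc_trend(pred, truth, s=2)
            rows = []
            for p, tr in zip(pred, truth):
                for t in tr:
                    lab = oracles.trend_label_brute(tr, t, 2)
                    if lab == "excluded":
                        continue
                    rows.append((lab,
                                 min(p[k + 1] - p[k] for k in range(t - 2, t)),
                                 min(p[k] - p[k + 1] for k in range(t - 2, t))))
            for key, col, cls in (("auc_trend_up", 1, "increasing"),
                                  ("auc_trend_down", 2, "decreasing")):
                expected = oracles.pairwise_auc(
                    [r[col] for r in rows], [r[0] == cls for r in rows])
                if expected is None:
                    assert out[key] is None
                else:
                    assert out[key] == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# Distributional checks
# ---------------------------------------------------------------------------


class TestKs:
    def test_identical_pools_zero(self):
        assert ks_statistic([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_disjoint_pools_one(self):
        assert ks_statistic([1.0, 2.0], [10.0, 11.0]) == 1.0

    def test_small_example(self):
        assert ks_statistic([1.0, 3.0], [1.0, 2.0]) == pytest.approx(0.5)

    def test_matches_brute_force_ecdf(self, rng):
        a = list(np.round(rng.uniform(0, 10, 40), 1))
        b = list(np.round(rng.uniform(2, 12, 25), 1))
        assert ks_statistic(a, b) == pytest.approx(oracles.ks_brute(a, b), abs=1e-12)

    def test_empty_pool_missing(self):
        assert ks_statistic([], [1.0]) is None


class TestCorrelationPreservation:
    def _cells(self, rng, n=40, rho=0.7):
        cov = [[1, rho], [rho, 1]]
        xy = rng.multivariate_normal([10, 5], cov, size=n)
        keys = [(i, 1) for i in range(n)]
        truth = {"a": dict(zip(keys, xy[:, 0])), "b": dict(zip(keys, xy[:, 1])),
                 "c": {k: float(rng.uniform(0, 1)) for k in keys}}
        return truth, keys

    def test_identical_panels_give_unit_r2(self, rng):
        truth, _ = self._cells(rng)
        r2, info = correlation_preservation(truth, truth, ["a", "b", "c"])
        assert r2 == pytest.approx(1.0)
        assert info["n_pairs"] == 3

    def test_constant_predictions_flagged_missing(self, rng):
        truth, keys = self._cells(rng)
        pred = {v: {k: 1.0 for k in keys} for v in truth}
        r2, info = correlation_preservation(truth, pred, ["a", "b", "c"])
        assert r2 is None
        assert all(reason == "zero variance" for _, _, reason in info["skipped"])

    def test_matches_brute_force(self, rng):
        truth, keys = self._cells(rng)
        pred = {v: {k: val + rng.normal(0, 0.3) for k, val in cells.items()}
                for v, cells in truth.items()}
        r2, _ = correlation_preservation(truth, pred, ["a", "b", "c"])
        expected = oracles.correlation_r2_brute(truth, pred, ["a", "b", "c"])
        assert r2 == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# Full report assembly
# ---------------------------------------------------------------------------


class TestEvaluateForecasts:
    def test_sex_conditional_ranges_and_bleed_event(self):
        config = MetricConfig(
            sigmas={"hemoglobin": 1.0},
            reference_ranges={"hemoglobin": {"by": "sex", "M": (14.0, 18.0),
                                             "F": (12.0, 16.0)}},
            trend_window=2,
            events={"hemoglobin_bleed": ("hemoglobin", (7.5, math.inf))},
        )
        examples = [
            make_example(truth={"hemoglobin": {1: 13.0}}, statics={"sex": "M"},
                         baselines={"hemoglobin": 13.5}, horizon=(1, 2)),
            make_example(truth={"hemoglobin": {1: 7.0}}, statics={"sex": "F"},
                         baselines={"hemoglobin": 9.0}, horizon=(1, 2)),
            make_example(truth={"hemoglobin": {1: 15.0}}, statics={"sex": "F"},
                         baselines={"hemoglobin": 15.0}, horizon=(1, 2)),
        ]
        forecasts = [{"hemoglobin": {1: 13.2, 2: 13.0}},
                     {"hemoglobin": {1: 7.4, 2: 7.2}},
                     {"hemoglobin": {1: 14.8, 2: 14.9}}]
        report = evaluate_forecasts(examples, forecasts, config, ["hemoglobin"])
        ref = report.per_target["hemoglobin"]["reference"]
        # 13.0 is low for a male but 15.0 is normal for a female
        assert ref["counts"] == {"low": 2, "normal": 1, "high": 0}
        bleed = report.per_target["hemoglobin_bleed"]["event"]
        assert bleed["counts"]["low"] == 1  # only the 7.0 truth point
        assert bleed["auc_low"] == 1.0  # the 7.4 forecast ranks lowest

    def test_report_serialization_is_deterministic(self, rng):
        config = MetricConfig(sigmas={"hemoglobin": 1.0}, trend_window=2)
        examples = [make_example()]
        forecasts = [{"hemoglobin": {1: 11.0, 2: 10.0, 3: 10.5, 4: 10.0}}]
        a = evaluate_forecasts(examples, forecasts, config, ["hemoglobin"]).to_json()
        b = evaluate_forecasts(examples, forecasts, config, ["hemoglobin"]).to_json()
        assert a == b
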