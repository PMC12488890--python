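import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twinforecast.data_model import (
    ForecastExample,
    Observation,
    PatientRecord,
    TaskConfig,
    VariableSpec,
    bin_last_observed,
    build_examples,
    fit_outlier_bounds,
    filter_outliers_two_step,
    icu_task,
    make_landmark_examples,
    nsclc_registry,
    read_cohort,
    split_patients,
    write_cohort,
)

from conftest import make_record


# ---------------------------------------------------------------------------
# Variable registry
# ---------------------------------------------------------------------------


class TestVariableSpec:
    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            VariableSpec("x", reference_range=(5.0, 5.0))

    def test_categorical_target_rejected(self):
        with pytest.raises(ValueError):
            VariableSpec("x", value_kind="categorical", role="target")

    def test_sex_conditional_range_resolution(self):
        reg = nsclc_registry()
        hb = reg["hemoglobin"]
        assert hb.range_for({"sex": "M"}) == (14.0, 18.0)
        assert hb.range_for({"sex": "F"}) == (12.0, 16.0)
        assert hb.range_for({}) is None
        assert reg["leukocytes"].range_for() == (4.5, 11.0)


# ---------------------------------------------------------------------------
# Binning: last observed value per bin
# ---------------------------------------------------------------------------


class TestBinning:
    def test_single_observation_identity(self):
        rec = make_record(observations=[Observation("hb", 3, 5.0)])
        out = bin_last_observed(rec, 7.0)
        assert [(o.variable, o.time, o.value) for o in out.observations] == [("hb", 0, 5.0)]

    def test_last_value_wins_within_bin(self):
        rec = make_record(observations=[Observation("hb", 1, 5.0), Observation("hb", 3, 7.0)])
        out = bin_last_observed(rec, 7.0)
        assert [(o.time, o.value) for o in out.observations] == [(0, 7.0)]

    def test_idempotent(self):
        rec = make_record(observations=[Observation("hb", 1, 5.0), Observation("hb", 9, 7.0)])
        once = bin_last_observed(rec, 7.0)
        twice = bin_last_observed(once, 7.0)
        assert [(o.variable, o.time, o.value) for o in twice.observations] == [
            (o.variable, o.time, o.value) for o in once.observations
        ]

    def test_nonfinite_time_rejected(self):
        with pytest.raises(ValueError):
            Observation("hb", float("nan"), 5.0)

    def test_matches_brute_force_on_random_record(self, rng):
        obs = [
            Observation(f"v{int(rng.integers(4))}", float(rng.uniform(-30, 60)),
                        float(np.round(rng.uniform(0, 20), 1)))
            for _ in range(500)
        ]
        rec = make_record(observations=obs)
        out = bin_last_observed(rec, 7.0)
        # brute force: group by (variable, bin), keep value at the max raw time
        expected = {}
        for o in sorted(rec.observations, key=lambda o: o.time):
            b = math.floor(o.time / 7.0)
            expected[(o.variable, b)] = o.value
        got = {(o.variable, o.time): o.value for o in out.observations}
        assert got == expected


# ---------------------------------------------------------------------------
# Two-step outlier filter
# ---------------------------------------------------------------------------


class TestOutlierFilter:
    def test_constant_values_flagged_degenerate(self):
        report = fit_outlier_bounds({"hb": [1.0] * 20})
        b = report.bounds["hb"]
        assert b.degenerate and b.n_removed_train == 0
        cohort = [make_record(observations=[Observation("hb", 0, 1.0)], binned=True)]
        out, rep = filter_outliers_two_step({"hb": [1.0] * 20}, cohort)
        assert out[0].observations[0].value == 1.0

    def test_extreme_value_removed_in_step_one(self):
        # values {1.0}x20 + {100.0}: mean 5.714, sd(ddof=1) 21.6 -> 3sd = 64.9
        values = [1.0] * 20 + [100.0]
        report = fit_outlier_bounds({"hb": values})
        b = report.bounds["hb"]
        assert b.n_removed_train == 1
        assert b.step1_high == pytest.approx(5.7143 + 64.86, abs=0.05)
        # step-2 statistics computed on survivors only (all 1.0 -> degenerate)
        assert b.mean2 == pytest.approx(1.0)
        assert b.degenerate

    def test_step2_bounds_use_survivors_only(self):
        values = [10.0, 11.0, 12.0, 13.0, 14.0] * 8 + [500.0]
        report = fit_outlier_bounds({"hb": values})
        b = report.bounds["hb"]
        survivors = np.array([v for v in values if v != 500.0])
        assert b.mean2 == pytest.approx(survivors.mean())
        assert b.sd2 == pytest.approx(survivors.std(ddof=1))

    def test_standard_normal_tail_fraction(self):
        r = np.random.default_rng(7)
        values = r.standard_normal(10_000)
        report = fit_outlier_bounds({"z": values})
        b = report.bounds["z"]
        frac = b.n_removed_train / 10_000
        assert frac == pytest.approx(0.0027, abs=0.002)
        # applying to a cohort: survivors end inside the (grid-snapped) clip bounds
        cohort = [make_record(observations=[Observation("z", t, float(v))
                                            for t, v in enumerate(values[:500])], binned=True)]
        out, _ = filter_outliers_two_step({"z": values}, cohort)
        for o in out[0].observations:
            assert b.clip_low <= o.value <= b.clip_high

    def test_categorical_and_uncovered_variables_untouched(self):
        cohort = [make_record(observations=[
            Observation("therapy", 0, "chemo"), Observation("other", 0, 1e9)], binned=True)]
        out, _ = filter_outliers_two_step({"hb": [1.0, 2.0, 3.0]}, cohort)
        assert [(o.variable, o.value) for o in out[0].observations] == [
            ("other", 1e9), ("therapy", "chemo")]


# ---------------------------------------------------------------------------
# Patient-level splitting
# ---------------------------------------------------------------------------


def _cohort_of(n, attr=None, rng=None):
    records = []
    for i in range(n):
        statics = {}
        if attr is not None:
            statics["grp"] = attr(i)
        records.append(make_record(patient_id=f"P{i:04d}", statics=statics))
    return records


class TestSplitPatients:
    def test_exact_sizes_and_disjoint(self):
        split = split_patients(_cohort_of(10), (0.8, 0.1, 0.1), seed=0)
        assert (len(split.train), len(split.val), len(split.test)) == (8, 1, 1)
        assert not (set(split.train) & set(split.val) & set(split.test))

    def test_deterministic_given_seed(self):
        cohort = _cohort_of(57)
        a = split_patients(cohort, seed=123)
        b = split_patients(cohort, seed=123)
        assert a.as_dict() == b.as_dict()
        c = split_patients(cohort, seed=124)
        assert a.as_dict() != c.as_dict()

    def test_stratified_mix_tracks_fractions(self):
        cohort = _cohort_of(1000, attr=lambda i: "a" if i % 10 < 3 else "b")
        split = split_patients(cohort, (0.8, 0.1, 0.1), strata=["grp"], seed=5)
        statics = {r.patient_id: r.statics["grp"] for r in cohort}
        for part in (split.train, split.val, split.test):
            frac_a = sum(statics[p] == "a" for p in part) / len(part)
            assert abs(frac_a - 0.3) <= 0.02

    def test_disjoint_and_covering_over_many_cohorts(self):
        r = np.random.default_rng(0)
        for trial in range(100):
            n = int(r.integers(3, 40))
            cohort = _cohort_of(n)
            split = split_patients(cohort, seed=int(r.integers(1 << 30)))
            ids = [p for part in (split.train, split.val, split.test) for p in part]
            assert len(ids) == len(set(ids)) == n
            assert set(ids) == {rec.patient_id for rec in cohort}

    def test_tiny_stratum_warns_and_still_covers(self):
        cohort = _cohort_of(11, attr=lambda i: "rare" if i == 0 else "common")
        with pytest.warns(UserWarning):
            split = split_patients(cohort, strata=["grp"], seed=1)
        assert sorted(split.train + split.val + split.test) == sorted(
            r.patient_id for r in cohort)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            split_patients(_cohort_of(5), (0.5, 0.2, 0.2))


# ---------------------------------------------------------------------------
# Landmark example construction
# ---------------------------------------------------------------------------


class TestLandmarkExamples:
    def test_no_therapy_events_yields_no_examples(self, simple_task):
        rec = make_record(observations=[Observation("hemoglobin", 0, 12.0)], binned=True)
        assert make_landmark_examples(rec, simple_task) == []

    def test_icu_style_fixed_history(self):
        task = icu_task(("resp_rate",))
        obs = [Observation("resp_rate", t, float(np.round(14 + 0.1 * t, 1))) for t in range(48)]
        rec = make_record(observations=obs, binned=True)
        examples = make_landmark_examples(rec, task)
        assert len(examples) == 1
        ex = examples[0]
        assert ex.t0 == 23
        assert max(int(o.time) for o in ex.history) == 0
        assert len(ex.history) == 24
        assert sorted(ex.truth["resp_rate"]) == list(range(1, 25))

    def test_two_therapy_lines_no_leakage(self, simple_task):
        obs = [Observation("therapy", 0, "chemo"), Observation("therapy", 6, "immuno")]
        for t in range(-3, 11):
            obs.append(Observation("hemoglobin", t, float(np.round(12 + 0.1 * t, 1))))
        rec = make_record(observations=obs, binned=True)
        examples = make_landmark_examples(rec, simple_task)
        assert len(examples) == 2
        for ex, t0 in zip(examples, (0, 6)):
            assert ex.t0 == t0
            for o in ex.history:
                assert o.time <= 0
            for target, cells in ex.truth.items():
                for off, val in cells.items():
                    assert off in simple_task.horizon_offsets
                    # truth value really comes from the future of the record
                    raw = {int(r.time): r.value for r in rec.observations
                           if r.variable == target}
                    assert raw[t0 + off] == val

    def test_examples_without_future_targets_dropped(self, simple_task):
        rec = make_record(observations=[
            Observation("therapy", 0, "chemo"), Observation("hemoglobin", -1, 12.0)],
            binned=True)
        examples, acc = build_examples([rec], simple_task)
        assert examples == []
        assert acc["n_dropped_empty"] == 1

    def test_unbinned_record_rejected(self, simple_task):
        rec = make_record(observations=[Observation("therapy", 0, "chemo")])
        with pytest.raises(ValueError):
            make_landmark_examples(rec, simple_task)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_history_never_after_landmark(self, seed):
        r = np.random.default_rng(seed)
        obs = [Observation("therapy", int(r.integers(-2, 8)), "chemo")]
        for _ in range(int(r.integers(1, 30))):
            obs.append(Observation("hemoglobin", int(r.integers(-8, 14)),
                                   float(np.round(r.uniform(8, 16), 1))))
        rec = PatientRecord("P0", {}, obs, binned=True)
        task = TaskConfig(targets=("hemoglobin",), horizon_offsets=(1, 2, 3),
                          landmark_policy="therapy_start", landmark_variable="therapy")
        for ex in make_landmark_examples(rec, task):
            assert all(o.time <= 0 for o in ex.history)
            assert all(off in (1, 2, 3) for off in ex.truth.get("hemoglobin", {}))


# ---------------------------------------------------------------------------
# Cohort I/O
# ---------------------------------------------------------------------------


def test_cohort_csv_round_trip(tmp_path, rng):
    cohort = []
    for i in range(5):
        obs = [Observation("hb", int(t), float(np.round(rng.uniform(8, 16), 1)))
               for t in rng.integers(0, 20, size=8)]
        obs.append(Observation("therapy", 3, "chemo"))
        cohort.append(PatientRecord(f"P{i}", {"sex": "F", "status": 1.0}, obs, binned=True))
    write_cohort(cohort, tmp_path / "obs.csv", tmp_path / "statics.csv")
    back = read_cohort(tmp_path / "obs.csv", tmp_path / "statics.csv", binned=True)
    assert len(back) == len(cohort)
    for a, b in zip(sorted(cohort, key=lambda r: r.patient_id), back):
        assert a.patient_id == b.patient_id
        assert a.statics == b.statics
        assert [(o.variable, o.time, o.value) for o in a.observations] == [
            (o.variable, o.time, o.value) for o in b.observations]


def test_example_dict_round_trip(rng):
    from conftest import random_example

    for _ in range(20):
        ex = random_example(rng)
        back = ForecastExample.from_dict(ex.to_dict())
        assert back.truth == ex.truth
        assert back.baseline_values == ex.baseline_values
        assert [(o.variable, o.time, o.value) for o in back.history] == [
            (o.variable, o.time, o.value) for o in ex.history]
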