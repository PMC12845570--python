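"""Offline analysis: activity pooling, ratios, paired test, asymmetry,
regression and compliance — each checked against hand-computed oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from infantfeedback.analysis import (
    active_passive_test,
    activity_table,
    analyze_sessions,
    clinical_correlation,
    compliance_metrics,
    daily_ratios,
    session_activity,
    side_asymmetry_index,
)
from infantfeedback.errors import AnalysisError, EmptyInputError
from infantfeedback.imu_io import LIMBS
from infantfeedback.study_tables import clinical_scores, training_journal

from conftest import make_session, make_stream


class TestSessionActivity:
    def test_constant_streams_give_their_magnitude(self, full_session):
        assert session_activity(full_session).activity == pytest.approx(5.0)

    def test_sensor_order_irrelevant(self, full_session):
        a = session_activity(full_session).activity
        full_session.streams = dict(reversed(list(full_session.streams.items())))
        assert session_activity(full_session).activity == a

    def test_odd_count_pooled_median(self):
        # one sample per limb except left_hand with two: pooled {1,2,3,4,5}
        dt = 1 / 26
        mags = {"left_hand": [1.0, 2.0], "right_hand": [3.0], "left_foot": [4.0], "right_foot": [5.0]}
        streams = {}
        for limb, vals in mags.items():
            n = len(vals)
            t = np.arange(n) * dt
            gyro = np.column_stack([vals, np.zeros(n), np.zeros(n)])
            streams[limb] = make_stream(limb, t=t)
            streams[limb].gyro = gyro
        session = make_session(stream_overrides=streams)
        for limb, s in streams.items():
            session.streams[limb] = s
        session.planned_duration_s = dt  # tiny constructed session counts as complete
        assert session_activity(session).activity == pytest.approx(3.0)

    def test_incomplete_session_rejected_on_direct_call(self):
        session = make_session(duration_s=90.0, interrupted=True)
        with pytest.raises(AnalysisError, match="not complete"):
            session_activity(session)


class TestDailyRatios:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["session_id", "day", "mode", "activity", "n_samples"])

    def test_equal_activity_gives_unity(self):
        df = self._table(
            [("a", 1, "active", 5.0, 10), ("b", 1, "passive", 5.0, 10)]
        )
        assert daily_ratios(df)["ratio"].iloc[0] == pytest.approx(1.0)

    def test_hand_computed_ratio(self):
        df = self._table(
            [
                ("a", 1, "active", 4.0, 10),
                ("b", 1, "active", 6.0, 10),
                ("c", 1, "passive", 2.0, 10),
                ("d", 1, "passive", 3.0, 10),
            ]
        )
        assert daily_ratios(df)["ratio"].iloc[0] == pytest.approx(2.0)  # 5 / 2.5

    def test_day_missing_a_mode_is_flagged_not_dropped(self):
        df = self._table([("a", 1, "active", 4.0, 10), ("b", 2, "active", 4.0, 10),
                          ("c", 2, "passive", 2.0, 10)])
        out = daily_ratios(df)
        assert len(out) == 2
        day1 = out[out["day"] == 1].iloc[0]
        assert np.isnan(day1["ratio"]) and "missing passive" in day1["note"]

    def test_zero_passive_mean_flagged(self):
        df = self._table([("a", 1, "active", 4.0, 10), ("b", 1, "passive", 0.0, 10)])
        out = daily_ratios(df)
        assert np.isnan(out["ratio"].iloc[0]) and "zero" in out["note"].iloc[0]

    def test_no_day_labels_is_error(self):
        df = self._table([("a", None, "active", 4.0, 10)])
        with pytest.raises(AnalysisError, match="day labels"):
            daily_ratios(df)


class TestPairedTest:
    def test_all_zero_differences(self):
        res = active_passive_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_constant_nonzero_differences_degenerate(self):
        with pytest.warns(UserWarning, match="zero variance"):
            res = active_passive_test([2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0])
        assert res.degenerate
        assert res.t == np.inf
        assert 0 < res.p <= np.finfo(float).tiny

    def test_matches_textbook_formula(self):
        diffs = np.array([2.0, -1.0, 3.0, 0.0, 1.0])
        passive = np.array([5.0, 5.0, 5.0, 5.0, 5.0])
        res = active_passive_test(passive + diffs, passive)
        t_oracle = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(diffs.size))
        from scipy import stats

        p_oracle = 2 * stats.t.sf(abs(t_oracle), df=diffs.size - 1)
        assert res.t == pytest.approx(t_oracle)
        assert res.p == pytest.approx(p_oracle)
        assert res.df == 4

    def test_fewer_than_two_pairs_rejected(self):
        with pytest.raises(AnalysisError):
            active_passive_test([1.0], [0.5])


class TestAsymmetry:
    def test_balanced_sides_give_zero(self):
        assert side_asymmetry_index([make_session(left_mag=4.0, right_mag=4.0)]).index == 0.0

    def test_silent_left_gives_plus_one(self):
        res = side_asymmetry_index([make_session(left_mag=0.0, right_mag=2.0)])
        assert res.index == pytest.approx(1.0)

    def test_hand_computed_index(self):
        res = side_asymmetry_index([make_session(left_mag=1.0, right_mag=3.0)])
        assert res.index == pytest.approx(0.5)  # (3-1)/(3+1)
        assert res.left == pytest.approx(1.0) and res.right == pytest.approx(3.0)

    def test_index_bounded_and_antisymmetric(self):
        res_r = side_asymmetry_index([make_session(left_mag=1.0, right_mag=5.0)])
        res_l = side_asymmetry_index([make_session(left_mag=5.0, right_mag=1.0)])
        assert -1 <= res_l.index <= 1 <= res_r.index + 1
        assert res_r.index == pytest.approx(-res_l.index)

    def test_all_sessions_excluded_is_error(self):
        with pytest.raises(AnalysisError, match="interrupted"):
            side_asymmetry_index([make_session(duration_s=50.0, interrupted=True)])

    def test_both_sides_silent_is_error(self):
        with pytest.raises(AnalysisError, match="zero median"):
            side_asymmetry_index([make_session(left_mag=0.0, right_mag=0.0)])


class TestClinicalCorrelation:
    def test_collinear_points_r2_one(self):
        res = clinical_correlation([0, 1, 2, 3], [1, 3, 5, 7])
        assert res.r2 == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)

    def test_constant_response_r2_zero(self):
        res = clinical_correlation([0, 1, 2, 3], [4, 4, 4, 4])
        assert res.r2 == pytest.approx(0.0)

    def test_matches_normal_equations_oracle(self):
        x = np.array([0.0, 1.0, 2.0])
        y = np.array([1.0, 3.0, 4.0])
        res = clinical_correlation(x, y)
        # closed form: slope = Sxy/Sxx, r2 = Sxy^2/(Sxx*Syy)
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        sxx = np.sum((x - x.mean()) ** 2)
        syy = np.sum((y - y.mean()) ** 2)
        assert res.slope == pytest.approx(sxy / sxx)
        assert res.intercept == pytest.approx(y.mean() - res.slope * x.mean())
        assert res.r2 == pytest.approx(sxy**2 / (sxx * syy))

    def test_constant_predictor_rejected(self):
        with pytest.raises(AnalysisError, match="constant"):
            clinical_correlation([2, 2, 2], [1, 2, 3])


class TestCompliance:
    def test_single_infant_minutes_per_day(self):
        journal = pd.DataFrame(
            [{"infant_id": 1, "days_trained": 93, "hours_trained": 22.6}]
        )
        summary = compliance_metrics(journal, recommended_days=104)
        assert summary.per_infant["minutes_per_day"].iloc[0] == pytest.approx(22.6 * 60 / 93)
        assert round(summary.per_infant["minutes_per_day"].iloc[0], 1) == 14.6

    def test_bundled_cohort_reproduces_reported_compliance(self):
        summary = compliance_metrics(training_journal(), recommended_days=104)
        assert round(summary.mean_minutes_per_day, 1) == 13.3
        assert round(summary.sd_minutes_per_day, 1) == 1.8
        assert summary.n_meeting == 7 and summary.n_total == 12
        assert round(summary.pct_meeting) == 58

    def test_zero_days_excluded_from_rate_but_counted(self):
        journal = pd.DataFrame(
            [
                {"infant_id": 1, "days_trained": 0, "hours_trained": 0.0},
                {"infant_id": 2, "days_trained": 60, "hours_trained": 15.0},
            ]
        )
        summary = compliance_metrics(journal, recommended_days=104)
        assert np.isnan(summary.per_infant["minutes_per_day"].iloc[0])
        assert summary.n_total == 2 and summary.n_meeting == 1
        assert summary.pct_meeting == pytest.approx(50.0)

    def test_all_zero_days(self):
        journal = pd.DataFrame(
            [{"infant_id": i, "days_trained": 0, "hours_trained": 0.0} for i in range(3)]
        )
        summary = compliance_metrics(journal, recommended_days=104)
        assert summary.pct_meeting == 0.0
        assert np.isnan(summary.mean_minutes_per_day)

    def test_empty_journal_rejected(self):
        with pytest.raises(EmptyInputError):
            compliance_metrics(pd.DataFrame(columns=["infant_id", "days_trained", "hours_trained"]))

    def test_clinical_table_shape(self):
        df = clinical_scores()
        assert len(df) == 12
        assert set(df.columns) == {"infant_id", "corrected_age_weeks", "dominant_hand", "aims"}
        assert df.loc[df["infant_id"] == 14, "aims"].iloc[0] == 27


class TestPipelineFilters:
    def test_mixed_log_counts_and_reasons(self, mixed_quality_log):
        table, decisions = activity_table(mixed_quality_log)
        assert len(table) == 7  # 10 - 2 interrupted - 1 short
        reasons = {d.session_id: d.reason for d in decisions if not d.included}
        assert reasons["interrupted-1"] == "interrupted"
        assert "incomplete" in reasons["short-1"]
        asym = side_asymmetry_index(mixed_quality_log)
        assert asym.n_sessions_used == 6  # dropout additionally excluded
        dropped = {d.session_id for d in asym.excluded}
        assert "dropout-1" in dropped

    def test_report_itemizes_every_session(self, mixed_quality_log):
        report = analyze_sessions(mixed_quality_log)
        assert report["n_sessions"] == 10 and report["n_complete"] == 7
        assert len(report["filter_decisions"]) == 10
        assert "mean_daily_ratio" in report
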