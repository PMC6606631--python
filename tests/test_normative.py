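"""Published table, normative prediction, sweeps and clinical thresholds."""

import warnings

import numpy as np
import pytest

import gaitnorm as gn
from gaitnorm.normative import (
    DEFAULT_MEDIANS,
    ExtrapolationWarning,
    OrderRepairWarning,
    classify_clinical,
    clinical_timing_threshold,
    complete_derivatives,
    contribution_range,
    contribution_report,
    repair_timing_order,
    sweep_predictor,
)


class TestPublishedTable:
    def test_his2_timing_row(self, published_table):
        rec = published_table.get("HIS2", "timing")
        assert rec.intercept == 37.0166
        assert rec.coefficients["speed"] == -10.9165
        assert rec.coefficients["sex"] == -0.2067
        assert not rec.retained("age") and not rec.retained("bmi")

    def test_ans2_timing_intercept_only(self, published_table):
        rec = published_table.get("ANS2", "timing")
        assert rec.intercept == 7.2097 and rec.n_predictors == 0
        assert not rec.is_constant

    def test_cycle_end_rows_duplicate_cycle_start(self, published_table):
        for start, end in (("HIS1", "HIS6"), ("KNS1", "KNS8"), ("ANS1", "ANS7")):
            a = published_table.get(start, "angle")
            b = published_table.get(end, "angle")
            assert a.intercept == b.intercept and a.coefficients == b.coefficients

    def test_full_coverage(self, published_table):
        assert len(published_table) == 42  # 21 key-points x (timing, angle)
        assert published_table.source == "published"


class TestPredictKeypoints:
    def test_his2_timing_dot_product(self, published_table):
        p = gn.PredictorVector(0.40, 40, 0, 24)
        states = gn.predict_keypoints(published_table, p, joints=["hip"])["hip"]
        his2 = states[1]
        assert his2.timing == pytest.approx(37.0166 - 10.9165 * 0.40, abs=1e-9)

    def test_his1_angle_dot_product(self, published_table):
        p = gn.PredictorVector(0.45, 38, 1, 24)
        states = gn.predict_keypoints(published_table, p, joints=["hip"])["hip"]
        expected = 9.1713 + 20.4474 * 0.45 - 0.0393 * 38 - 4.8 + 0.4698 * 24
        assert states[0].angle == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(23.354, abs=5e-4)

    def test_ans2_timing_constant_under_any_predictors(self, published_table):
        for p in (gn.PredictorVector(0.25, 20, 0, 18), gn.PredictorVector(0.65, 65, 1, 30)):
            states = gn.predict_keypoints(published_table, p, joints=["ankle"])["ankle"]
            assert states[1].timing == 7.2097

    def test_extrapolation_flagged_outside_envelope(self, published_table):
        with pytest.warns(ExtrapolationWarning):
            gn.predict_keypoints(published_table, gn.PredictorVector(0.1, 40, 0, 24))
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            gn.predict_keypoints(published_table, gn.PredictorVector(0.45, 40, 0, 24))

    def test_missing_record_is_an_error(self, published_table):
        partial = gn.CoefficientTable(
            [r for r in published_table if r.keypoint_id != "KNS5"]
        )
        with pytest.raises(KeyError):
            gn.predict_keypoints(partial, gn.PredictorVector(0.45, 40, 0, 24))


class TestPredictWaveforms:
    def test_deterministic(self, published_table, median_predictors):
        w1 = gn.predict_waveforms(published_table, median_predictors)
        w2 = gn.predict_waveforms(published_table, median_predictors)
        for joint in gn.JOINTS:
            assert np.array_equal(w1[joint].values, w2[joint].values)

    def test_passes_through_predicted_keypoints_at_knots(
        self, published_table, median_predictors
    ):
        states = gn.predict_keypoints(published_table, median_predictors)["knee"]
        wf = gn.predict_waveforms(published_table, median_predictors)["knee"]
        from gaitnorm.reconstruct import evaluate_piecewise

        completed = complete_derivatives(states)
        for s in completed:
            assert evaluate_piecewise(completed, np.array([s.timing]))[0] == pytest.approx(
                s.angle, abs=1e-9
            )

    def test_knee_swing_peak_grows_with_speed(self, published_table):
        # printed KNS6 speed coefficient is positive
        peaks = []
        for v in np.linspace(0.25, 0.65, 9):
            states = gn.predict_keypoints(
                published_table, gn.PredictorVector(v, 38, 1, 24)
            )["knee"]
            peaks.append(states[5].angle)
        assert np.all(np.diff(peaks) > 0)

    def test_median_prediction_inside_population_corridor(
        self, published_table, noisy_dataset, median_predictors
    ):
        wfs = gn.predict_waveforms(published_table, median_predictors)
        for joint in gn.JOINTS:
            stack = np.stack(
                [
                    t.waveforms[joint].values
                    for t in noisy_dataset.trials
                    if 0.3 <= t.predictor.v_star <= 0.6
                ]
            )
            lo = stack.mean(axis=0) - stack.std(axis=0)
            hi = stack.mean(axis=0) + stack.std(axis=0)
            inside = (wfs[joint].values >= lo) & (wfs[joint].values <= hi)
            assert inside.mean() > 0.8


class TestSweepsAndContributions:
    def test_sex_sweep_has_two_points(self, published_table):
        assert len(sweep_predictor(published_table, "sex")) == 2

    def test_age_sweep_has_fifteen_points(self, published_table):
        sweep = sweep_predictor(published_table, "age", value_range=(19, 67))
        assert len(sweep) == 15
        assert sweep[0][0] == 19 and sweep[-1][0] == 67

    def test_degenerate_range_rejected(self, published_table):
        with pytest.raises(ValueError):
            sweep_predictor(published_table, "bmi", value_range=(24, 24))

    def test_bmi_endpoints_differ_by_coefficient_times_width(self, published_table):
        sweep = sweep_predictor(published_table, "bmi", value_range=(17, 31))
        first = sweep[0][1]["hip"][0].angle
        last = sweep[-1][1]["hip"][0].angle
        assert last - first == pytest.approx(0.4698 * 14, abs=1e-9)

    def test_sex_contribution_over_hip_extrema(self, published_table):
        out = contribution_range(
            published_table, "sex", "hip", ["HIS3", "HIS4", "HIS5"]
        )
        assert round(out["angle"], 1) == 6.4

    def test_bmi_contribution_over_hip_keypoints(self, published_table):
        out = contribution_range(
            published_table, "bmi", "hip", ["HIS1", "HIS3", "HIS6"], (17, 31)
        )
        assert out["angle"] == pytest.approx(0.4698 * 14)
        assert round(out["angle"], 1) == 6.6

    def test_ns_predictor_contributes_zero(self, published_table):
        out = contribution_range(published_table, "age", "ankle", ["ANS1"], (19, 67))
        assert out["angle"] == 0.0

    def test_sweeping_ns_predictor_leaves_parameter_unchanged(self, published_table):
        sweep = sweep_predictor(published_table, "age", value_range=(19, 67))
        angles = {v: states["ankle"][0].angle for v, states in sweep}  # ANS1 angle: age NS
        assert len(set(angles.values())) == 1

    def test_wrong_joint_keypoint_rejected(self, published_table):
        with pytest.raises(ValueError):
            contribution_range(published_table, "sex", "hip", ["KNS2"])

    def test_contribution_report_labels(self, published_table):
        report = contribution_report(published_table, "speed", value_range=(0.2, 0.7))
        frame = report.frame.set_index("keypoint_id")
        # HIS4 timing: |-21.823| * 0.5 = 10.9 % GC -> clinically significant
        assert frame.loc["HIS4", "timing_label"] == "significant"
        assert frame.loc["HIS4", "delta_timing_pct"] == pytest.approx(21.823 * 0.5)


class TestClinicalThresholds:
    @pytest.mark.parametrize(
        "dt, da, expected",
        [
            (1.0, 1.5, ("not_significant", "none")),
            (4.0, 3.5, ("significant", "consider")),
            (0.0, 6.0, ("not_significant", "may_mislead")),
        ],
    )
    def test_label_bands(self, dt, da, expected):
        assert classify_clinical(dt, da) == expected

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            classify_clinical(-1.0, 0.0)

    def test_timing_threshold_from_event_detection_window(self):
        # 4 frames at 120 Hz over a 1.10 s cycle -> 3 % of gait cycle
        assert clinical_timing_threshold(4, 120.0, 1.10) == 3.0


class TestOrderRepair:
    def test_ordered_states_untouched(self):
        states = [
            gn.KeyPointState("A", 1, 0.0),
            gn.KeyPointState("B", 40, 1.0),
            gn.KeyPointState("C", 101, 0.0),
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            repaired = repair_timing_order(states)
        assert [s.timing for s in repaired] == [1, 40, 101]

    def test_inverted_states_reordered_with_warning(self):
        states = [
            gn.KeyPointState("A", 1, 0.0),
            gn.KeyPointState("B", 50, 1.0),
            gn.KeyPointState("C", 49, 2.0),
            gn.KeyPointState("D", 101, 0.0),
        ]
        with pytest.warns(OrderRepairWarning):
            repaired = repair_timing_order(states)
        t = [s.timing for s in repaired]
        assert all(b >= a + 1 for a, b in zip(t, t[1:]))
        assert t[0] == 1 and t[-1] == 101
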