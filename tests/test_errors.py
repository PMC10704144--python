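"""Windowing, rule-based detection, feedback mapping, correction ledger."""

import numpy as np
import pytest

from tests.conftest import sine_series
from vestkit.errors import (
    ConfigurationError,
    ErrorEvent,
    ErrorThresholds,
    cohort_error_rates,
    detect_errors,
    feedback_for,
    summarize_correction,
    window_series,
)
from vestkit.kinematics import calibrate_neutral, to_relative
from vestkit.prescriptions import ExercisePrescription
from vestkit.session import SessionRecord
from vestkit.synthetic import ErrorInjection, SyntheticSpec, generate_exercise_series


def relative_record(labeled, condition="app"):
    s = labeled.series
    if s.reference == "absolute":
        s = to_relative(s, calibrate_neutral(s))
    return SessionRecord("S1", condition, labeled.prescription, s)


def event(window, etype, severity=0.5):
    return ErrorEvent(window, window * 7.0, (window + 1) * 7.0, etype, severity)


class TestWindowing:
    def test_sixty_seconds_gives_eight_windows_with_merged_tail(self):
        s = sine_series(duration=60.0)
        windows = window_series(s, 7.0)
        assert len(windows) == 8
        assert windows[-1].t_start == 49.0
        assert windows[-1].t_end == pytest.approx(60.0, abs=0.05)

    def test_fourteen_seconds_two_full_windows(self):
        windows = window_series(sine_series(duration=14.0), 7.0)
        assert len(windows) == 2
        assert windows[0].t_end == 7.0
        assert windows[1].t_end == pytest.approx(14.0, abs=0.05)

    def test_three_seconds_too_short(self):
        with pytest.raises(ValueError, match="shorter than half"):
            window_series(sine_series(duration=3.0), 7.0)

    def test_long_partial_window_kept(self):
        windows = window_series(sine_series(duration=13.0), 7.0)
        assert len(windows) == 2  # 6 s remainder >= 2/3 window stands alone
        assert windows[1].t_start == 7.0


class TestDetection:
    thresholds = ErrorThresholds.from_prescription(
        ExercisePrescription.default("vor_yaw")
    )

    def test_clean_prescribed_trial_no_events(self, vor_prescription):
        lab = generate_exercise_series(
            SyntheticSpec(prescription=vor_prescription, seed=1)
        )
        assert detect_errors(relative_record(lab), self.thresholds) == []

    def test_too_far_lands_in_window_three(self, vor_prescription):
        lab = generate_exercise_series(
            SyntheticSpec(
                prescription=vor_prescription, seed=2,
                injections=(ErrorInjection("too_far", 21.0, 28.0, 18.0),),
            )
        )
        events = detect_errors(relative_record(lab), self.thresholds)
        far = [e for e in events if e.error_type == "too_far"]
        assert len(far) == 1
        assert far[0].window_index == 3  # floor(21 / 7)
        assert far[0].severity > 0

    def test_chin_motion_detected_without_too_far(self, vor_prescription):
        lab = generate_exercise_series(
            SyntheticSpec(
                prescription=vor_prescription, seed=3,
                injections=(ErrorInjection("chin_motion", 42.0, 49.0, 15.0),),
            )
        )
        events = detect_errors(relative_record(lab), self.thresholds)
        assert {e.error_type for e in events} == {"chin_motion"}
        assert [e.window_index for e in events if e.error_type == "chin_motion"] == [6]

    def test_too_fast_detected_in_its_window_only(self, vor_prescription):
        lab = generate_exercise_series(
            SyntheticSpec(
                prescription=vor_prescription, seed=4,
                injections=(ErrorInjection("too_fast", 21.0, 28.0, 2.0),),
            )
        )
        events = detect_errors(relative_record(lab), self.thresholds)
        fast = [e for e in events if e.error_type == "too_fast"]
        assert [e.window_index for e in fast] == [3]

    def test_missing_thresholds_is_configuration_error(self, vor_prescription):
        lab = generate_exercise_series(SyntheticSpec(prescription=vor_prescription))
        with pytest.raises(ConfigurationError):
            detect_errors(relative_record(lab), None)

    def test_non_vor_exercise_rejected(self):
        p = ExercisePrescription.default("ws_ml")
        lab = generate_exercise_series(SyntheticSpec.clean(p))
        with pytest.raises(ValueError, match="VOR"):
            detect_errors(relative_record(lab), self.thresholds)

    def test_determinism(self, vor_prescription):
        lab = generate_exercise_series(
            SyntheticSpec(
                prescription=vor_prescription, seed=5,
                injections=(ErrorInjection("jerky", 35.0, 42.0, 10.0),),
            )
        )
        record = relative_record(lab)
        assert detect_errors(record, self.thresholds) == detect_errors(
            record, self.thresholds
        )


class TestFeedback:
    @pytest.mark.parametrize(
        "etype,text",
        [
            ("too_far", "Don't move your head so far"),
            ("too_fast", "Slow down your head movement"),
            ("jerky", "Keep your head movement smooth"),
            ("chin_motion", "Keep your chin still"),
        ],
    )
    def test_fixed_mapping(self, etype, text):
        msg = feedback_for(event(0, etype))
        assert msg.text == text
        assert msg.modality == "both"

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            feedback_for("wobbling")


class TestCorrectionLedger:
    def test_early_errors_count_as_corrected(self):
        s = summarize_correction([event(1, "too_far"), event(2, "too_far")], 8)
        assert s.made["too_far"] and s.corrected["too_far"]
        assert not s.not_corrected["too_far"]

    def test_errors_to_the_end_not_corrected(self):
        events = [event(i, "jerky") for i in range(8)]
        s = summarize_correction(events, 8)
        assert s.made["jerky"] and s.not_corrected["jerky"]
        assert not s.corrected["jerky"]

    def test_no_events_all_false(self):
        s = summarize_correction([], 8)
        for etype in ("too_far", "too_fast", "jerky", "chin_motion"):
            assert not s.made[etype]
            assert not s.corrected[etype] and not s.not_corrected[etype]

    def test_boundary_window_counts_as_corrected(self):
        # last flagged window at n_windows - 3 still leaves two clean windows
        assert summarize_correction([event(5, "too_far")], 8).corrected["too_far"]
        assert not summarize_correction([event(6, "too_far")], 8).corrected["too_far"]

    def test_raster_grid_matches_events(self):
        s = summarize_correction([event(2, "chin_motion"), event(4, "chin_motion")], 8)
        assert s.window_grid["chin_motion"] == [
            False, False, True, False, True, False, False, False
        ]


class TestCohortRates:
    def test_counting_example(self):
        summaries = []
        for i in range(10):
            if i < 3:
                summaries.append(summarize_correction([event(1, "too_far")], 8))
            elif i < 4:
                summaries.append(summarize_correction([event(7, "too_far")], 8))
            else:
                summaries.append(summarize_correction([], 8))
        rates = cohort_error_rates(summaries)
        assert rates["too_far"] == {
            "made": 0.40, "corrected": 0.30, "not_corrected": pytest.approx(0.10)
        }

    def test_all_clean_all_zero(self):
        rates = cohort_error_rates([summarize_correction([], 8) for _ in range(5)])
        for row in rates.values():
            assert row == {"made": 0.0, "corrected": 0.0, "not_corrected": 0.0}

    def test_conservation_holds_for_every_row(self):
        rng = np.random.default_rng(0)
        summaries = []
        for _ in range(30):
            events = [
                event(int(w), etype)
                for etype in ("too_far", "jerky")
                for w in rng.choice(8, size=rng.integers(0, 4), replace=False)
            ]
            summaries.append(summarize_correction(events, 8))
        for row in cohort_error_rates(summaries).values():
            assert row["corrected"] + row["not_corrected"] == pytest.approx(row["made"])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cohort_error_rates([])
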