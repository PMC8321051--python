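import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mvtrack import (SigmaSeries, classify_disease, count_rapid_transitions,
                     gap_threshold, label_states)


def states_from(labels: str):
    """'OCOC' -> StateSeries-compatible labelling via explicit sigmas."""
    sigma = np.array([5.0 if ch == "O" else 1.0 for ch in labels])
    return label_states(sigma, gap_threshold(sigma))


class TestGapThreshold:
    def test_largest_shift_in_sorted_series(self):
        thr = gap_threshold(np.array([3, 1, 10, 2, 11.0]))
        assert thr.value == 3.0
        assert not thr.degenerate

    def test_all_equal_is_degenerate(self):
        thr = gap_threshold(np.array([5.0, 5.0, 5.0]))
        assert thr.value == 5.0
        assert thr.degenerate

    def test_two_values(self):
        assert gap_threshold(np.array([1.0, 9.0])).value == 1.0

    def test_tie_takes_smallest_index(self):
        # gaps 4 and 4: the lower one wins
        assert gap_threshold(np.array([0.0, 4.0, 8.0])).value == 0.0

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            gap_threshold(np.array([1.0]))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=2, max_size=30))
    def test_threshold_is_a_series_member(self, sigma):
        thr = gap_threshold(np.array(sigma))
        assert thr.value in sigma

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.lists(st.floats(0, 100, allow_nan=False), min_size=3, max_size=30),
        st.floats(-50, 50, allow_nan=False),
    )
    def test_labels_invariant_under_constant_shift(self, sigma, shift):
        sigma = np.array(sigma)
        base = label_states(sigma, gap_threshold(sigma))
        shifted = label_states(sigma + shift, gap_threshold(sigma + shift))
        assert np.array_equal(base.is_open, shifted.is_open)


class TestLabelStates:
    def test_threshold_splits_series(self):
        states = label_states(np.array([1, 2, 3, 10, 11.0]), 3.0)
        assert states.labels == ["closed", "closed", "closed", "open", "open"]

    def test_sigma_equal_to_threshold_is_closed(self):
        states = label_states(np.array([3.0, 4.0]), 3.0)
        assert states.labels[0] == "closed"

    def test_minimum_sigma_frame_is_always_closed(self, rng):
        for _ in range(10):
            sigma = rng.random(12) * 20
            states = label_states(sigma, gap_threshold(sigma))
            assert not states.is_open[np.argmin(sigma)]
            assert states.open_fraction + states.closed_fraction == pytest.approx(1.0)


class TestRapidTransitions:
    @pytest.mark.parametrize(
        "labels, expected",
        [
            ("OCOC", 2),
            ("OOOO", 0),
            ("OOCCO", 0),
            ("OCOCOC", 4),
            ("COOCC", 0),
        ],
    )
    def test_window_counts(self, labels, expected):
        is_open = np.array([ch == "O" for ch in labels])
        assert count_rapid_transitions(is_open) == expected

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            count_rapid_transitions(np.array([True, False]))


class TestClassifyDisease:
    def test_mostly_closed_triggers_rule_2(self):
        verdict = classify_disease(states_from("C" * 90 + "O" * 10))
        assert verdict.label == "diseased"
        assert verdict.rules_triggered == (2,)
        assert verdict.closed_fraction == pytest.approx(0.9)

    def test_mostly_open_triggers_rule_3(self):
        verdict = classify_disease(states_from("O" * 90 + "C" * 10))
        assert verdict.rules_triggered == (3,)

    def test_exactly_85_percent_is_healthy(self):
        verdict = classify_disease(states_from("C" * 85 + "O" * 15))
        assert verdict.label == "healthy"

    def test_six_rapid_windows_in_100_frames_triggers_rule_1(self):
        # an 8-frame alternating burst has 7 state changes -> 6 overlapping
        # rapid windows, one more than the 5% budget of 100 frames
        labels = "OCOCOCOC" + "C" * 46 + "O" * 46
        assert len(labels) == 100
        verdict = classify_disease(states_from(labels))
        assert verdict.transition_count == 6
        assert verdict.rules_triggered == (1,)

    def test_five_rapid_windows_in_100_frames_is_within_budget(self):
        # 6 changes -> 5 rapid windows, not strictly above 0.05 * 100
        labels = "COCOCOC" + "C" * 46 + "O" * 47
        assert len(labels) == 100
        verdict = classify_disease(states_from(labels))
        assert verdict.transition_count == 5
        assert 1 not in verdict.rules_triggered

    def test_balanced_long_runs_are_healthy(self):
        labels = ("O" * 15 + "C" * 15) * 2
        verdict = classify_disease(states_from(labels))
        assert verdict.label == "healthy"
        assert verdict.rules_triggered == ()
        assert verdict.transition_count == 0

    def test_degenerate_all_equal_sigma_reads_diseased_too_closed(self):
        sigma = np.full(20, 7.0)
        states = label_states(sigma, gap_threshold(sigma))
        verdict = classify_disease(states)
        assert states.degenerate
        assert verdict.rules_triggered == (2,)
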