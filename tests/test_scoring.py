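"""Per-trial measures: coverage, look-away gaps, first look, DLS."""

import numpy as np
import pytest

from antlook.paradigm import Side
from antlook.scoring import (
    dls,
    first_look,
    head_before_window,
    looked_during_cue,
    max_consecutive_lookaway,
    on_scene_coverage,
    score_trial,
    window_times,
)

from conftest import (
    grid_max_lookaway_ms,
    grid_on_scene_ms,
    grid_window_times_ms,
    make_seq,
    make_timeline,
    random_small_sequence,
)

SCENE = (0.5, 0.65)  # on scene, outside every named AOI
OFF = (-0.3, 0.5)


def _w(aois, side):
    return aois.window_only[side].centre()


def _box(aois, side):
    outer, inner = aois.window_box[side], aois.window_only[side]
    return (outer.x0 + outer.x1) / 2, (inner.y1 + outer.y1) / 2


class TestCoverage:
    periods = ((200, 900), (1200, 2600))

    def test_full_coverage_equals_period_lengths(self, aois):
        seq = make_seq([(0, 3000, *SCENE)])
        assert on_scene_coverage(seq, aois, self.periods) == 700 + 1400

    def test_half_inside_fixation_clipped(self, aois):
        seq = make_seq([(2350, 2850, *SCENE)])  # 250 ms inside period 2
        assert on_scene_coverage(seq, aois, self.periods) == 250

    def test_off_scene_sequence_scores_zero(self, aois):
        seq = make_seq([(0, 3000, *OFF)])
        assert on_scene_coverage(seq, aois, self.periods) == 0

    def test_coverage_plus_uncovered_conserved(self, aois):
        rng = np.random.default_rng(11)
        total = sum(b - a for a, b in self.periods)
        for _ in range(50):
            seq = random_small_sequence(rng)
            cov = on_scene_coverage(seq, aois, self.periods)
            unc = grid_total_uncovered(seq, aois, self.periods)
            assert cov + unc == total


def grid_total_uncovered(seq, aois, periods):
    return sum(b - a for a, b in periods) - grid_on_scene_ms(seq, aois, periods)


class TestLookaway:
    periods = ((200, 900), (1200, 2600))

    def test_full_coverage_no_gap(self, aois):
        seq = make_seq([(0, 3000, *SCENE)])
        assert max_consecutive_lookaway(seq, aois, self.periods) == 0

    def test_long_gap_inside_one_period(self, aois):
        # hole [1300, 2900) clips to a 1300 ms run inside period 2
        seq = make_seq([(0, 1300, *SCENE), (2900, 3000, *SCENE)])
        assert max_consecutive_lookaway(seq, aois, self.periods) == 1300
        # nothing in period 2 at all: the whole 1400 ms period is one run
        seq = make_seq([(0, 1000, *SCENE)])
        assert max_consecutive_lookaway(seq, aois, self.periods) == 1400

    def test_gaps_do_not_bridge_periods(self, aois):
        # 700 ms gap at end of period 1 and 900 at start of period 2
        seq = make_seq([(0, 200, *SCENE), (2100, 2600, *SCENE)])
        assert max_consecutive_lookaway(seq, aois, self.periods) == 900

    def test_off_scene_fixation_counts_as_lookaway(self, aois):
        seq = make_seq([(0, 1200, *SCENE), (1200, 2600, *OFF)])
        assert max_consecutive_lookaway(seq, aois, self.periods) == 1400

    def test_merge_tolerance_forgives_short_gaps(self, aois):
        seq = make_seq([(200, 1700, *SCENE), (1780, 2600, *SCENE)])
        assert max_consecutive_lookaway(seq, aois, self.periods) == 80
        assert max_consecutive_lookaway(seq, aois, self.periods, merge_tolerance=100) == 0


class TestCue:
    def test_fixation_spanning_cue(self, aois):
        tl = make_timeline()
        assert looked_during_cue(make_seq([(0, 3000, *SCENE)]), aois, tl)

    def test_fixation_ending_at_cue_onset_misses(self, aois):
        tl = make_timeline()  # cue [500, 750)
        assert not looked_during_cue(make_seq([(0, 500, *SCENE)]), aois, tl)
        assert looked_during_cue(make_seq([(0, 501, *SCENE)]), aois, tl)

    def test_off_scene_during_cue(self, aois):
        tl = make_timeline()
        assert not looked_during_cue(make_seq([(400, 900, *OFF)]), aois, tl)


class TestFirstLook:
    def test_box_landing_counts_for_first_look(self, aois):
        tl = make_timeline(condition="FB1")  # correct right
        seq = make_seq([(600, 900, *_box(aois, "right"))])
        assert first_look(seq, aois, tl) is Side.RIGHT

    def test_head_only_gives_none(self, aois):
        tl = make_timeline()
        seq = make_seq([(600, 900, *aois.head.centre())])
        assert first_look(seq, aois, tl) is Side.NONE

    def test_half_open_period_boundary(self, aois):
        tl = make_timeline()  # interest [500, 2000)
        inside = make_seq([(1999, 2100, *_w(aois, "left"))])
        outside = make_seq([(2000, 2100, *_w(aois, "left"))])
        assert first_look(inside, aois, tl) is Side.LEFT
        assert first_look(outside, aois, tl) is Side.NONE

    def test_fixation_ongoing_at_cue_onset_not_counted(self, aois):
        tl = make_timeline()
        seq = make_seq([(300, 1200, *_w(aois, "left")), (1300, 1500, *_w(aois, "right"))])
        assert first_look(seq, aois, tl) is Side.RIGHT

    def test_consistency_between_1750_and_2750_periods(self, aois):
        # an early qualifying fixation decides first look under both periods
        short = make_timeline(duration=6000, period_of_interest=1750)
        long = make_timeline(duration=6000, period_of_interest=2750)
        seq = make_seq([(700, 1000, *_w(aois, "right")), (2500, 2800, *_w(aois, "left"))])
        assert first_look(seq, aois, short) is first_look(seq, aois, long) is Side.RIGHT


class TestDls:
    def test_formula(self, aois):
        tl = make_timeline(condition="FB1")  # correct right
        seq = make_seq([(600, 900, *_w(aois, "right")), (1000, 1100, *_w(aois, "left"))])
        assert dls(seq, aois, tl) == pytest.approx(0.75)

    def test_all_correct_side(self, aois):
        tl = make_timeline(condition="FB2")  # correct left
        seq = make_seq([(600, 900, *_w(aois, "left"))])
        assert dls(seq, aois, tl) == 1.0

    def test_box_but_never_window_is_undefined(self, aois):
        tl = make_timeline()
        seq = make_seq([(600, 900, *_box(aois, "right"))])
        assert dls(seq, aois, tl) is None
        assert first_look(seq, aois, tl) is Side.RIGHT  # still a first look

    def test_clipped_at_period_boundaries(self, aois):
        tl = make_timeline(condition="FB1")  # interest [500, 2000)
        seq = make_seq([(1800, 2400, *_w(aois, "right"))])
        assert window_times(seq, aois, tl) == (200, 0)

    def test_order_invariance(self, aois):
        tl = make_timeline(condition="FB1")
        a = make_seq([(600, 900, *_w(aois, "right")), (1000, 1100, *_w(aois, "left"))])
        b = make_seq([(600, 700, *_w(aois, "left")), (900, 1200, *_w(aois, "right"))])
        # same spans of window time, different order
        assert dls(a, aois, tl) == dls(b, aois, tl)


class TestHeadBeforeWindow:
    def test_head_then_window(self, aois):
        tl = make_timeline()
        seq = make_seq(
            [(600, 800, *aois.head.centre()), (900, 1200, *_w(aois, "right"))]
        )
        assert head_before_window(seq, aois, tl)

    def test_window_first(self, aois):
        tl = make_timeline()
        seq = make_seq(
            [(600, 800, *_w(aois, "right")), (900, 1200, *aois.head.centre())]
        )
        assert not head_before_window(seq, aois, tl)

    def test_vacuous_without_window_fixation(self, aois):
        tl = make_timeline()
        seq = make_seq([(600, 800, *aois.head.centre())])
        assert not head_before_window(seq, aois, tl)


class TestGridOracleEquivalence:
    """Interval algebra vs a brute-force 1 ms-grid oracle on random data."""

    def test_coverage_gap_and_dls_match_grid_oracle(self, aois):
        rng = np.random.default_rng(2024)
        tl = make_timeline(condition="FB1")
        periods = tl.key_periods
        for _ in range(150):
            seq = random_small_sequence(rng)
            assert on_scene_coverage(seq, aois, periods) == grid_on_scene_ms(
                seq, aois, periods
            )
            assert max_consecutive_lookaway(seq, aois, periods) == grid_max_lookaway_ms(
                seq, aois, periods
            )
            assert window_times(seq, aois, tl) == grid_window_times_ms(seq, aois, tl)


class TestScoreTrial:
    def test_composite_matches_individual_operations(self, aois):
        rng = np.random.default_rng(7)
        tl = make_timeline(condition="FB2")
        for _ in range(25):
            seq = random_small_sequence(rng)
            ts = score_trial(seq, aois, tl)
            assert ts.cumulative_on_scene_in_key_periods == on_scene_coverage(
                seq, aois, tl.key_periods
            )
            assert ts.max_consecutive_lookaway_in_key_periods == max_consecutive_lookaway(
                seq, aois, tl.key_periods
            )
            assert ts.looked_during_cue == looked_during_cue(seq, aois, tl)
            assert ts.first_look_side == first_look(seq, aois, tl)
            assert ts.first_window_fixation_after_head == head_before_window(seq, aois, tl)
            assert (ts.correct_window_time, ts.incorrect_window_time) == window_times(
                seq, aois, tl
            )
            assert ts.dls == dls(seq, aois, tl)
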