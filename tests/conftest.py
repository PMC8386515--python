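"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from antlook.cohort import ParticipantRecord
from antlook.events import FixationEvent, FixationSequence
from antlook.paradigm import (
    Side,
    TrialTimeline,
    load_aois,
    load_paradigm_config,
)
from antlook.scoring import TrialScore


@pytest.fixture(scope="session")
def paradigm_config() -> dict:
    return load_paradigm_config()


@pytest.fixture(scope="session")
def aois(paradigm_config):
    return load_aois(paradigm_config)


def make_seq(events, participant="p1", role="test") -> FixationSequence:
    """Build a sequence from (onset, offset, x, y) tuples."""
    return FixationSequence(
        participant, role, tuple(FixationEvent(*ev) for ev in events)
    )


def make_timeline(
    role="test",
    condition="FB1",
    duration=4000,
    cue_onset=500,
    cue_duration=250,
    period_of_interest=1500,
    key_periods=((200, 900), (1200, 2600)),
    correct_side=None,
) -> TrialTimeline:
    """A compact trial timeline for desk-scale scoring tests."""
    from antlook.paradigm import CORRECT_SIDES

    side = correct_side or CORRECT_SIDES[(role, condition if role == "test" else None)]
    return TrialTimeline(
        trial_role=role,
        condition=condition if role == "test" else None,
        duration=duration,
        cue_onset=cue_onset,
        cue_duration=cue_duration,
        period_of_interest=period_of_interest,
        key_periods=key_periods,
        correct_side=side,
    )


def make_score(
    fam_coverage=9000,
    lookaway=0,
    cue=True,
    first=Side.RIGHT,
    head_first=True,
    correct_ms=500,
    incorrect_ms=200,
) -> TrialScore:
    return TrialScore(
        cumulative_on_scene_in_key_periods=fam_coverage,
        max_consecutive_lookaway_in_key_periods=lookaway,
        looked_during_cue=cue,
        first_look_side=first,
        first_window_fixation_after_head=head_first,
        correct_window_time=correct_ms,
        incorrect_window_time=incorrect_ms,
    )


def make_participant(
    pid,
    site="CPH",
    condition="FB1",
    procedural=False,
    fam_coverage=9000,
    test_lookaway=0,
    test_first=Side.RIGHT,
    fam2_first=Side.RIGHT,
    cue_test=True,
    cue_fam2=True,
) -> ParticipantRecord:
    """A participant whose scores pass everything unless told otherwise."""
    if procedural:
        return ParticipantRecord(pid, site, condition, procedural_error=True)
    half = fam_coverage // 2
    return ParticipantRecord(
        pid,
        site,
        condition,
        scores={
            "fam1": make_score(fam_coverage=half),
            "fam2": make_score(fam_coverage=fam_coverage - half, cue=cue_fam2,
                               first=fam2_first),
            "test": make_score(lookaway=test_lookaway, cue=cue_test,
                               first=test_first),
        },
    )


# ---------------------------------------------------------------------------
# independent oracles


def grid_on_scene_ms(seq, aois, periods) -> int:
    """1 ms-grid coverage oracle: count covered milliseconds per period."""
    total = 0
    sc = aois.scene
    spans = [
        (ev.onset, ev.offset)
        for ev in seq.events
        if sc.x0 <= ev.x < sc.x1 and sc.y0 <= ev.y < sc.y1
    ]
    for start, end in periods:
        for t in range(start, end):
            if any(a <= t < b for a, b in spans):
                total += 1
    return total


def grid_max_lookaway_ms(seq, aois, periods) -> int:
    """1 ms-grid oracle for the longest uncovered run within one period."""
    sc = aois.scene
    spans = [
        (ev.onset, ev.offset)
        for ev in seq.events
        if sc.x0 <= ev.x < sc.x1 and sc.y0 <= ev.y < sc.y1
    ]
    longest = 0
    for start, end in periods:
        run = 0
        for t in range(start, end):
            if any(a <= t < b for a, b in spans):
                run = 0
            else:
                run += 1
                longest = max(longest, run)
    return longest


def grid_window_times_ms(seq, aois, timeline) -> tuple[int, int]:
    """1 ms-grid oracle for window-only looking times in the period of interest."""
    times = {"left": 0, "right": 0}
    start, end = timeline.interest_interval
    for t in range(start, end):
        for ev in seq.events:
            if ev.onset <= t < ev.offset:
                for side in ("left", "right"):
                    r = aois.window_only[side]
                    if r.x0 <= ev.x < r.x1 and r.y0 <= ev.y < r.y1:
                        times[side] += 1
                break
    correct = timeline.correct_side.value
    return times[correct], times["left" if correct == "right" else "right"]


def binomial_p_oracle(k: int, n: int, p0: Fraction = Fraction(1, 2)) -> Fraction:
    """Exact-fraction enumeration of the point-probability two-tailed p."""
    q0 = 1 - p0

    def pmf(j: int) -> Fraction:
        return comb(n, j) * p0**j * q0 ** (n - j)

    obs = pmf(k)
    fudge = obs * Fraction(1, 10**9)  # mirror float tie handling
    return sum(pmf(j) for j in range(n + 1) if pmf(j) <= obs + fudge)


def fisher_p_oracle(table) -> Fraction:
    """Exact-fraction enumeration over all 2x2 tables with the same margins."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)

    def pmf(k: int) -> Fraction:
        return Fraction(comb(r1, k) * comb(r2, c1 - k), denom)

    obs = pmf(a)
    fudge = obs * Fraction(1, 10**9)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= obs + fudge)


def random_small_sequence(rng: np.random.Generator, duration=3000):
    """A randomized short fixation sequence mixing on/off-scene landings."""
    events = []
    t = int(rng.integers(0, 120))
    while t < duration - 40:
        dur = int(rng.integers(30, 400))
        off = min(t + dur, duration)
        x = float(rng.uniform(-0.3, 1.3))
        y = float(rng.uniform(-0.3, 1.3))
        events.append((t, off, x, y))
        t = off + int(rng.integers(0, 300))
    return make_seq(events)
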