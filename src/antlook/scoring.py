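"""Per-trial derived measures.

Everything here is interval arithmetic over a fixation sequence, an AOI set
and a trial timeline, using the package-wide half-open ``[onset, offset)``
convention in integer milliseconds:

* attention metrics over the key periods — cumulative on-scene fixation
  time and the longest consecutive look-away — which feed the exclusion
  cascade;
* whether the scene was fixated at all during the cue;
* the binary first-look measure: the side of the first window+box AOI
  fixated within the period of interest (fixation *onset* inside the
  period; a fixation already ongoing at cue onset is not a new orientation
  and does not count);
* the differential looking score (DLS): cumulative fixation time on the
  correct window-only AOI divided by the summed time on both window-only
  AOIs within the period of interest, fixations clipped at the period
  boundaries.  DLS is undefined when neither window was fixated.

"Looking away" means absence of on-scene fixation coverage: gaps between
fixations and fixations landing off-scene count equally.  A configurable
merge tolerance can forgive short gaps (e.g. blinks); the default is the
strict 0 ms.  Fixation landing points classify fixations (the landing
point, not the saccade path, decides AOI membership).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

from .events import FixationSequence
from .paradigm import AOISet, Side, TrialTimeline

Interval = tuple[int, int]


class _Classified(NamedTuple):
    """One fixation with its AOI membership resolved."""

    onset: int
    offset: int
    on_scene: bool
    head: bool
    window_box: str | None  # "left" / "right" / None
    window_only: str | None


def _classify(seq: FixationSequence, aois: AOISet) -> list[_Classified]:
    """Resolve AOI membership for every fixation in one pass.

    Equivalent to calling :func:`antlook.paradigm.aoi_hit` per event, but
    unpacked into plain comparisons: this runs inside simulation studies
    over hundreds of thousands of trials.
    """
    sc, hd = aois.scene, aois.head
    wol, wor = aois.window_only["left"], aois.window_only["right"]
    wbl, wbr = aois.window_box["left"], aois.window_box["right"]
    out = []
    for ev in seq.events:
        x, y = ev.x, ev.y
        on_scene = sc.x0 <= x < sc.x1 and sc.y0 <= y < sc.y1
        head = hd.x0 <= x < hd.x1 and hd.y0 <= y < hd.y1
        wb = wo = None
        if wbl.x0 <= x < wbl.x1 and wbl.y0 <= y < wbl.y1:
            wb = "left"
            if wol.x0 <= x < wol.x1 and wol.y0 <= y < wol.y1:
                wo = "left"
        elif wbr.x0 <= x < wbr.x1 and wbr.y0 <= y < wbr.y1:
            wb = "right"
            if wor.x0 <= x < wor.x1 and wor.y0 <= y < wor.y1:
                wo = "right"
        out.append(_Classified(ev.onset, ev.offset, on_scene, head, wb, wo))
    return out


@dataclass(frozen=True)
class TrialScore:
    """Derived measures for one participant x trial."""

    cumulative_on_scene_in_key_periods: int
    max_consecutive_lookaway_in_key_periods: int
    looked_during_cue: bool
    first_look_side: Side
    first_window_fixation_after_head: bool
    correct_window_time: int
    incorrect_window_time: int

    @property
    def dls(self) -> float | None:
        denom = self.correct_window_time + self.incorrect_window_time
        if denom == 0:
            return None
        return self.correct_window_time / denom


def _overlap(a: Interval, b: Interval) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _merge(spans: Iterable[Interval], tolerance: int = 0) -> list[Interval]:
    """Union of intervals, merging across gaps of at most ``tolerance`` ms."""
    out: list[Interval] = []
    for a, b in sorted(spans):
        if out and a - out[-1][1] <= tolerance:
            if b > out[-1][1]:
                out[-1] = (out[-1][0], b)
        else:
            out.append((a, b))
    return out


def _coverage(spans: Sequence[Interval], periods: Sequence[Interval]) -> int:
    return sum(_overlap(s, p) for s in spans for p in periods)


def _max_gap(spans: Sequence[Interval], periods: Sequence[Interval]) -> int:
    longest = 0
    for start, end in periods:
        cursor = start
        for a, b in spans:
            if b <= start:
                continue
            if a >= end:
                break
            a, b = max(a, start), min(b, end)
            if a - cursor > longest:
                longest = a - cursor
            if b > cursor:
                cursor = b
        if end - cursor > longest:
            longest = end - cursor
    return longest


def _scene_spans(cls: Sequence[_Classified], tolerance: int = 0) -> list[Interval]:
    return _merge(((c.onset, c.offset) for c in cls if c.on_scene), tolerance)


def on_scene_coverage(
    seq: FixationSequence, aois: AOISet, periods: Sequence[Interval]
) -> int:
    """Total ms of on-scene fixation inside the given (disjoint) periods."""
    return _coverage(_scene_spans(_classify(seq, aois)), periods)


def max_consecutive_lookaway(
    seq: FixationSequence,
    aois: AOISet,
    periods: Sequence[Interval],
    merge_tolerance: int = 0,
) -> int:
    """Longest uncovered run within any single key period, in ms.

    Look-away runs never bridge across distinct key periods: the intervals
    between periods are not scored.  Gaps of at most ``merge_tolerance`` ms
    between on-scene fixations are forgiven (treated as covered).
    """
    return _max_gap(_scene_spans(_classify(seq, aois), merge_tolerance), periods)


def looked_during_cue(
    seq: FixationSequence, aois: AOISet, timeline: TrialTimeline
) -> bool:
    """True iff at least 1 ms of on-scene fixation overlaps the cue interval."""
    cue = timeline.cue_interval
    return any(
        _overlap((c.onset, c.offset), cue) > 0
        for c in _classify(seq, aois)
        if c.on_scene
    )


def _first_window_box(
    cls: Sequence[_Classified], timeline: TrialTimeline
) -> _Classified | None:
    start, end = timeline.interest_interval
    for c in cls:
        if c.onset >= end:
            break
        if c.onset >= start and c.window_box is not None:
            return c
    return None


def first_look(seq: FixationSequence, aois: AOISet, timeline: TrialTimeline) -> Side:
    """Side of the first window+box AOI fixated within the period of interest."""
    found = _first_window_box(_classify(seq, aois), timeline)
    return Side.NONE if found is None else Side(found.window_box)


def head_before_window(
    seq: FixationSequence, aois: AOISet, timeline: TrialTimeline
) -> bool:
    """True iff a head-AOI fixation onset precedes the first window+box
    fixation onset, both within the period of interest.

    Vacuously false when there is no window+box fixation at all (such a
    participant is removed by the no-fixation criterion before this filter
    is consulted).
    """
    cls = _classify(seq, aois)
    found = _first_window_box(cls, timeline)
    if found is None:
        return False
    start = timeline.interest_interval[0]
    return any(start <= c.onset < found.onset and c.head for c in cls)


def window_times(
    seq: FixationSequence, aois: AOISet, timeline: TrialTimeline
) -> tuple[int, int]:
    """(correct, incorrect) window-only fixation ms, clipped to the period
    of interest."""
    return _window_times(_classify(seq, aois), timeline)


def _window_times(
    cls: Sequence[_Classified], timeline: TrialTimeline
) -> tuple[int, int]:
    poi = timeline.interest_interval
    times = {"left": 0, "right": 0}
    for c in cls:
        if c.window_only is None:
            continue
        clipped = _overlap((c.onset, c.offset), poi)
        if clipped:
            times[c.window_only] += clipped
    correct = timeline.correct_side.value
    incorrect = "left" if correct == "right" else "right"
    return times[correct], times[incorrect]


def dls(seq: FixationSequence, aois: AOISet, timeline: TrialTimeline) -> float | None:
    """Differential looking score, or None when no window was fixated."""
    correct, incorrect = window_times(seq, aois, timeline)
    total = correct + incorrect
    return None if total == 0 else correct / total


def score_trial(
    seq: FixationSequence,
    aois: AOISet,
    timeline: TrialTimeline,
    lookaway_merge_tolerance: int = 0,
) -> TrialScore:
    """Compute every per-trial measure in one classification pass."""
    cls = _classify(seq, aois)
    scene = _scene_spans(cls)
    scene_tol = (
        scene
        if lookaway_merge_tolerance == 0
        else _merge(scene, lookaway_merge_tolerance)
    )
    cue = timeline.cue_interval
    first = _first_window_box(cls, timeline)
    if first is None:
        first_side = Side.NONE
        after_head = False
    else:
        first_side = Side(first.window_box)
        start = timeline.interest_interval[0]
        after_head = any(
            start <= c.onset < first.onset and c.head for c in cls
        )
    correct, incorrect = _window_times(cls, timeline)
    return TrialScore(
        cumulative_on_scene_in_key_periods=_coverage(scene, timeline.key_periods),
        max_consecutive_lookaway_in_key_periods=_max_gap(
            scene_tol, timeline.key_periods
        ),
        looked_during_cue=any(_overlap(s, cue) > 0 for s in scene),
        first_look_side=first_side,
        first_window_fixation_after_head=after_head,
        correct_window_time=correct,
        incorrect_window_time=incorrect,
    )
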