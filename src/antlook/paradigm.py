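"""Paradigm semantics: AOI geometry, trial timelines and correct sides.

The task is a two-window / two-box anticipatory-looking paradigm.  An agent
watches a puppet hide a ball; a 1 s audio-visual cue then signals her
impending reach, and the measure is where the infant looks during the
*period of interest* — the 2750 ms from cue onset (1 s cue + 1750 ms delay,
matching the cue-to-reach lag in familiarization; 1750 ms is an alternative,
historically reported, variant).

Correct sides are fixed by the scenario: the agent reaches left in the
first familiarization and right in the second.  In the false-belief test
trials the agent's *belief* about the ball's location determines the
correct window: right in FB1 (she last saw it moved to the right box),
left in FB2 (she saw it placed in the left box and missed the transfer).

AOI rectangles and key-period intervals are measured properties of the
stimulus videos, not of the method; the defaults shipped in
``data/default_paradigm.json`` are documented placeholders with plausible
geometry and every value can be overridden by a user-supplied JSON file of
the same schema.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from typing import Any, Mapping

from .events import ConfigError

CONDITIONS = ("FB1", "FB2")


class Side(str, Enum):
    """Left/right of the stimulus frame, or no look at all."""

    LEFT = "left"
    RIGHT = "right"
    NONE = "none"


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle in stimulus-proportion coordinates.

    Containment is min-edge inclusive, max-edge exclusive, so two
    rectangles sharing an edge never both claim a point.
    """

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ConfigError(f"degenerate rectangle {self}")

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1

    def contains_rect(self, other: "Rect") -> bool:
        return (
            self.x0 <= other.x0
            and self.y0 <= other.y0
            and other.x1 <= self.x1
            and other.y1 <= self.y1
        )

    def disjoint(self, other: "Rect") -> bool:
        return (
            self.x1 <= other.x0
            or other.x1 <= self.x0
            or self.y1 <= other.y0
            or other.y1 <= self.y0
        )

    def centre(self) -> tuple[float, float]:
        return (self.x0 + self.x1) / 2, (self.y0 + self.y1) / 2


@dataclass(frozen=True)
class AOISet:
    """The paradigm's areas of interest.

    ``window_only`` rectangles cover just the windows (used for looking
    durations and the differential looking score); ``window_box``
    rectangles additionally span the box below each window (used for the
    binary first-look measure, approximating manual saccade coding that
    may have credited gaze passing through a window toward the box).
    """

    scene: Rect
    head: Rect
    window_only: Mapping[str, Rect]
    window_box: Mapping[str, Rect]

    def __post_init__(self) -> None:
        for mapping, name in ((self.window_only, "window_only"), (self.window_box, "window_box")):
            if set(mapping) != {"left", "right"}:
                raise ConfigError(f"{name} must have exactly 'left' and 'right' rectangles")
        for side in ("left", "right"):
            if not self.window_box[side].contains_rect(self.window_only[side]):
                raise ConfigError(f"window_only.{side} must lie inside window_box.{side}")
        for name, pair in (("window_only", self.window_only), ("window_box", self.window_box)):
            if not pair["left"].disjoint(pair["right"]):
                raise ConfigError(f"{name} left/right rectangles must be disjoint")
        for side in ("left", "right"):
            if not self.head.disjoint(self.window_box[side]):
                raise ConfigError(f"head must be disjoint from window_box.{side}")
        for name, rect in (
            ("head", self.head),
            ("window_box.left", self.window_box["left"]),
            ("window_box.right", self.window_box["right"]),
        ):
            if not self.scene.contains_rect(rect):
                raise ConfigError(f"AOI {name} must lie inside the scene")


@dataclass(frozen=True)
class TrialTimeline:
    """Event anchors for one trial role (x condition, for the test trial).

    All times are ms from trial start.  ``key_periods`` are the intervals
    during which the attention-based exclusion criteria apply (ball hiding
    events and the cue-to-reach span); ``period_of_interest`` is the
    anticipation-measurement window, anchored at ``cue_onset``.
    """

    trial_role: str
    condition: str | None
    duration: int
    cue_onset: int
    cue_duration: int
    period_of_interest: int
    key_periods: tuple[tuple[int, int], ...]
    correct_side: Side

    def __post_init__(self) -> None:
        if self.period_of_interest not in (1750, 2750):
            # deliberate overrides are allowed, but must be positive
            if self.period_of_interest <= 0:
                raise ConfigError("period_of_interest must be positive")
        if self.cue_duration <= 0:
            raise ConfigError("cue_duration must be positive")
        if self.cue_onset < 0 or self.cue_onset + self.period_of_interest > self.duration:
            raise ConfigError("period of interest extends past trial end")
        periods = tuple((int(a), int(b)) for a, b in self.key_periods)
        object.__setattr__(self, "key_periods", periods)
        last_end = None
        for a, b in periods:
            if not 0 <= a < b <= self.duration:
                raise ConfigError(f"key period [{a}, {b}) outside trial [0, {self.duration})")
            if last_end is not None and a < last_end:
                raise ConfigError("key periods must be pairwise disjoint and ordered")
            last_end = b

    @property
    def cue_interval(self) -> tuple[int, int]:
        return (self.cue_onset, self.cue_onset + self.cue_duration)

    @property
    def interest_interval(self) -> tuple[int, int]:
        return (self.cue_onset, self.cue_onset + self.period_of_interest)


# The agent's reach targets: familiarization trials are fixed by the videos;
# test-trial correctness follows the agent's (false) belief about the ball.
CORRECT_SIDES: dict[tuple[str, str | None], Side] = {
    ("fam1", None): Side.LEFT,
    ("fam2", None): Side.RIGHT,
    ("test", "FB1"): Side.RIGHT,
    ("test", "FB2"): Side.LEFT,
}


def _rect(spec: Any) -> Rect:
    return Rect(*map(float, spec))


def load_paradigm_config(source: str | dict | None = None) -> dict:
    """Load a paradigm configuration: shipped defaults, a JSON path, or a dict."""
    if source is None:
        text = resources.files("antlook.data").joinpath("default_paradigm.json").read_text()
        return json.loads(text)
    if isinstance(source, dict):
        return source
    with open(source, "r", encoding="utf-8") as fh:
        return json.load(fh)


def load_aois(config: dict | None = None) -> AOISet:
    cfg = config if config is not None else load_paradigm_config()
    a = cfg["aois"]
    return AOISet(
        scene=_rect(a["scene"]),
        head=_rect(a["head"]),
        window_only={s: _rect(a["window_only"][s]) for s in ("left", "right")},
        window_box={s: _rect(a["window_box"][s]) for s in ("left", "right")},
    )


def build_timeline(
    trial_role: str,
    condition: str | None = None,
    config: dict | None = None,
    period_of_interest: int | None = None,
) -> TrialTimeline:
    """Build the timeline for a trial role (and condition, for the test trial).

    ``period_of_interest`` overrides the configured value — used for the
    1750 ms analysis variant.
    """
    cfg = config if config is not None else load_paradigm_config()
    if trial_role not in ("fam1", "fam2", "test"):
        raise ConfigError(f"unknown trial role {trial_role!r}")
    cond = condition if trial_role == "test" else None
    if trial_role == "test" and cond not in CONDITIONS:
        raise ConfigError("test trials require condition 'FB1' or 'FB2'")
    t = cfg["timelines"][trial_role]
    poi = period_of_interest if period_of_interest is not None else int(t["period_of_interest"])
    return TrialTimeline(
        trial_role=trial_role,
        condition=cond,
        duration=int(t["duration"]),
        cue_onset=int(t["cue_onset"]),
        cue_duration=int(t["cue_duration"]),
        period_of_interest=poi,
        key_periods=tuple((int(a), int(b)) for a, b in t["key_periods"]),
        correct_side=CORRECT_SIDES[(trial_role, cond)],
    )


def aoi_hit(x: float, y: float, aois: AOISet) -> frozenset[str]:
    """All AOI labels whose rectangle contains (x, y).

    Labels: ``scene``, ``head``, ``window_only.left/right``,
    ``window_box.left/right``.  Nesting guarantees that any
    ``window_only.<s>`` hit is also a ``window_box.<s>`` hit.  Off-scene
    points return the empty set.
    """
    labels: set[str] = set()
    if aois.scene.contains(x, y):
        labels.add("scene")
    if aois.head.contains(x, y):
        labels.add("head")
    for side in ("left", "right"):
        if aois.window_box[side].contains(x, y):
            labels.add(f"window_box.{side}")
        if aois.window_only[side].contains(x, y):
            labels.add(f"window_only.{side}")
    return frozenset(labels)
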