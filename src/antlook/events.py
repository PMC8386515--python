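"""Fixation-event I/O and coordinate normalization.

Gaze data enter the pipeline as parsed *fixation events* — episodes of
stable gaze with an onset, offset and landing point, as emitted by an
eye-tracker's online event parser.  Two on-disk representations are
supported: EyeLink ASC event files (``EFIX`` lines delimited by ``MSG``
trial markers) and a tidy CSV dialect with one fixation per row.

Times are integer milliseconds relative to trial start; intervals are
half-open ``[onset, offset)``.  Landing points are pixels as recorded
until :func:`normalize_coordinates` maps them to stimulus-proportional
coordinates (origin top-left, y increasing downward), so that one AOI
configuration serves displays of different physical size.  Blinks and
saccades appear only implicitly, as gaps between fixations.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field, replace
from io import StringIO
from typing import IO, Iterable, Sequence

import pandas as pd

TRIAL_ROLES = ("fam1", "fam2", "test")

CSV_COLUMNS = ("participant", "trial_role", "onset_ms", "offset_ms", "x", "y")


class ParseError(ValueError):
    """Raised when an event stream is structurally malformed."""


class SchemaError(ValueError):
    """Raised when tabular input does not match the documented dialect."""


class ConfigError(ValueError):
    """Raised for invalid screen/AOI/timeline configuration."""


@dataclass(frozen=True)
class FixationEvent:
    """One fixation: half-open time span ``[onset, offset)`` plus landing point.

    Positions may be pixels (fresh from a parser) or stimulus proportions
    (after normalization); out-of-frame landing points are legitimate and
    represent off-scene looking.
    """

    onset: int
    offset: int
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError(
                f"fixation offset must exceed onset (got [{self.onset}, {self.offset}))"
            )
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("fixation landing point must be finite")

    @property
    def duration(self) -> int:
        return self.offset - self.onset


@dataclass(frozen=True)
class FixationSequence:
    """Ordered, non-overlapping fixations for one participant x trial."""

    participant: str
    trial_role: str
    events: tuple[FixationEvent, ...] = ()

    def __post_init__(self) -> None:
        if self.trial_role not in TRIAL_ROLES:
            raise SchemaError(
                f"unknown trial_role {self.trial_role!r}; expected one of {TRIAL_ROLES}"
            )
        object.__setattr__(self, "events", tuple(self.events))
        prev: FixationEvent | None = None
        for ev in self.events:
            if prev is not None:
                if ev.onset < prev.onset:
                    raise ParseError(
                        f"fixations out of order at onset {ev.onset} "
                        f"(participant {self.participant}, {self.trial_role})"
                    )
                if ev.onset < prev.offset:
                    raise ParseError(
                        f"overlapping fixations at [{ev.onset}, {ev.offset}) vs "
                        f"[{prev.onset}, {prev.offset}) "
                        f"(participant {self.participant}, {self.trial_role})"
                    )
            prev = ev

    def total_duration(self) -> int:
        """Summed fixation time in ms."""
        return sum(ev.duration for ev in self.events)


@dataclass(frozen=True)
class ScreenSpec:
    """Display geometry: full screen and the letterbox rectangle holding the movie.

    The stimulus rectangle is ``(left, top, width, height)`` in pixels.
    """

    width_px: int
    height_px: int
    stimulus_rect: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        left, top, w, h = self.stimulus_rect
        if self.width_px <= 0 or self.height_px <= 0:
            raise ConfigError("screen dimensions must be positive")
        if w <= 0 or h <= 0:
            raise ConfigError("stimulus rect must have positive area")
        if left < 0 or top < 0 or left + w > self.width_px or top + h > self.height_px:
            raise ConfigError("stimulus rect must lie within the screen")


@dataclass(frozen=True)
class MarkerSpec:
    """Configurable trial-boundary protocol for ASC ``MSG`` lines.

    ``trial_start`` is a regex applied to the MSG payload; its first group
    captures the trial role.  The exact marker strings written by a given
    Experiment Builder script vary between labs, hence the indirection.
    """

    trial_start: str = r"TRIAL_START\s+(\w+)"
    trial_end: str = r"TRIAL_END"


_EFIX_RE = re.compile(r"^EFIX\s+[LR]\s+(.*)$")
_MSG_RE = re.compile(r"^MSG\s+(\d+)\s+(.*)$")


def _parse_efix(line: str, lineno: int) -> tuple[int, int, float, float]:
    m = _EFIX_RE.match(line)
    if m is None:
        raise ParseError(f"line {lineno}: not an EFIX line: {line!r}")
    fields = m.group(1).split()
    # EFIX <eye> <start> <end> <dur> <x> <y> [<pupil>]
    if len(fields) < 5:
        raise ParseError(f"line {lineno}: malformed EFIX line (need >=5 fields): {line!r}")
    try:
        start = int(float(fields[0]))
        end = int(float(fields[1]))
        x = float(fields[3])
        y = float(fields[4])
    except ValueError as exc:
        raise ParseError(f"line {lineno}: malformed EFIX field: {line!r}") from exc
    return start, end, x, y


def read_asc_fixations(
    stream: IO[str] | str,
    participant: str,
    markers: MarkerSpec | None = None,
) -> list[FixationSequence]:
    """Parse EFIX fixation events from an EyeLink ASC event stream.

    Trials are delimited by MSG lines matching ``markers``; fixation times
    are rebased to the trial-start marker timestamp.  EFIX lines outside any
    trial, and trials whose role is not fam1/fam2/test, are skipped with a
    warning.  EFIX end times are treated as exclusive, matching the package's
    half-open convention.
    """
    markers = markers or MarkerSpec()
    start_re = re.compile(markers.trial_start)
    end_re = re.compile(markers.trial_end)
    if isinstance(stream, str):
        stream = StringIO(stream)

    sequences: list[FixationSequence] = []
    current_role: str | None = None
    current_t0 = 0
    current_events: list[FixationEvent] = []
    orphans = 0

    def flush() -> None:
        nonlocal current_role, current_events
        if current_role is not None:
            sequences.append(
                FixationSequence(participant, current_role, tuple(current_events))
            )
        current_role = None
        current_events = []

    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            continue
        msg = _MSG_RE.match(line)
        if msg is not None:
            ts, payload = int(msg.group(1)), msg.group(2)
            started = start_re.search(payload)
            if started is not None:
                if current_role is not None:
                    warnings.warn(
                        f"line {lineno}: trial {current_role!r} not closed before "
                        "next trial start; closing it implicitly"
                    )
                    flush()
                role = started.group(1)
                if role not in TRIAL_ROLES:
                    warnings.warn(f"line {lineno}: skipping trial with role {role!r}")
                    current_role = None
                else:
                    current_role = role
                    current_t0 = ts
                    current_events = []
            elif end_re.search(payload) and current_role is not None:
                flush()
            continue
        if line.startswith("EFIX"):
            start, end, x, y = _parse_efix(line, lineno)
            if current_role is None:
                orphans += 1
                continue
            onset = start - current_t0
            offset = end - current_t0
            if offset <= onset:
                raise ParseError(f"line {lineno}: EFIX span empty or reversed: {line!r}")
            current_events.append(FixationEvent(onset, offset, x, y))
        # SFIX/SSACC/ESACC/SBLINK/EBLINK/samples: ignored (fixations only)

    if current_role is not None:
        warnings.warn("stream ended inside an open trial; closing it implicitly")
        flush()
    if orphans:
        warnings.warn(f"{orphans} EFIX line(s) outside any marked trial were skipped")
    return sequences


def read_csv_fixations(stream: IO[str] | str) -> list[FixationSequence]:
    """Read the tidy CSV fixation dialect.

    Required columns: ``participant, trial_role, onset_ms, offset_ms, x, y``
    (UTF-8, "." decimal separator).  Rows with non-monotone onsets within a
    trial are re-sorted with a warning; true overlaps remain an error.
    """
    if isinstance(stream, str) and "\n" not in stream:
        df = pd.read_csv(stream, float_precision="round_trip")
    else:
        if isinstance(stream, str):
            stream = StringIO(stream)
        df = pd.read_csv(stream, float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    bad_roles = set(df["trial_role"].unique()) - set(TRIAL_ROLES)
    if bad_roles:
        raise SchemaError(
            f"unknown trial_role value(s) {sorted(map(str, bad_roles))}; "
            f"expected one of {TRIAL_ROLES}"
        )

    sequences: list[FixationSequence] = []
    for (pid, role), grp in df.groupby(["participant", "trial_role"], sort=True):
        onsets = grp["onset_ms"].to_numpy()
        if len(onsets) > 1 and (onsets[1:] < onsets[:-1]).any():
            warnings.warn(
                f"non-monotone onsets for participant {pid!r} {role}; re-sorting"
            )
            grp = grp.sort_values("onset_ms", kind="stable")
        events = tuple(
            FixationEvent(int(r.onset_ms), int(r.offset_ms), float(r.x), float(r.y))
            for r in grp.itertuples()
        )
        sequences.append(FixationSequence(str(pid), str(role), events))
    return sequences


def write_csv_fixations(sequences: Iterable[FixationSequence], stream: IO[str] | str) -> None:
    """Write sequences in the tidy CSV dialect (inverse of :func:`read_csv_fixations`)."""
    rows = [
        (seq.participant, seq.trial_role, ev.onset, ev.offset, ev.x, ev.y)
        for seq in sequences
        for ev in seq.events
    ]
    df = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
    # %.17g round-trips IEEE doubles exactly
    df.to_csv(stream, index=False, float_format="%.17g")


def normalize_coordinates(seq: FixationSequence, spec: ScreenSpec) -> FixationSequence:
    """Map pixel landing points to stimulus-proportional coordinates.

    ``x = (px_x - stim_left) / stim_width`` and analogously for y, so the
    stimulus frame maps to the unit square regardless of monitor size.
    Points beyond [-0.5, 1.5] are clamped to that bound with a warning;
    such looks are far off-scene either way.
    """
    left, top, w, h = spec.stimulus_rect
    clamped = 0

    def norm(v: float, lo: float, span: float) -> float:
        nonlocal clamped
        out = (v - lo) / span
        if out < -0.5 or out > 1.5:
            clamped += 1
            out = min(max(out, -0.5), 1.5)
        return out

    events = tuple(
        replace(ev, x=norm(ev.x, left, w), y=norm(ev.y, top, h)) for ev in seq.events
    )
    if clamped:
        warnings.warn(
            f"{clamped} coordinate(s) outside [-0.5, 1.5] clamped "
            f"(participant {seq.participant}, {seq.trial_role})"
        )
    return replace(seq, events=events)
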