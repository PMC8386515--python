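"""Preregistered exclusion cascade, ledger bookkeeping and analysis tables.

Participants are excluded, in order, if

1. ``procedural``            — there was a procedural error;
2. ``fam_attention``         — on-scene fixation during the familiarization
   key periods totalled less than 2 cumulative seconds (both trials);
3. ``test_lookaway``         — they looked away for more than 1.5
   consecutive seconds during the test key periods;
4. ``no_test_first_fixation``— no window/box fixation within the period of
   interest from cue onset in the test trial;
5. ``missed_cue``            — no on-scene fixation during the cue in the
   test or second familiarization trial;
6. ``fam2_incorrect``        — the first window+box look in the second
   familiarization trial was not to the correct (right) side.

Each excluded participant is attributed exactly one reason: the first
criterion failed, in the listed order (the counts a study reports are
mutually exclusive, and listed order is the only defensible precedence).
Participants failing only the final criterion form the "fam2-incorrect"
follow-up sample used in the condition x inclusion analysis.

The attention criteria (2) and (3) can be disabled to reproduce the
analysis variant that omits the look-away criteria.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .events import FixationSequence
from .paradigm import AOISet, Side, build_timeline
from .scoring import TrialScore, score_trial

SITES = ("CPH", "BP")

EXCLUSION_REASONS = (
    "procedural",
    "fam_attention",
    "test_lookaway",
    "no_test_first_fixation",
    "missed_cue",
    "fam2_incorrect",
)


class DataError(ValueError):
    """Raised when a participant record is unusable."""


@dataclass(frozen=True)
class ExclusionThresholds:
    """Attention/anticipation thresholds of the preregistered cascade (ms)."""

    fam_cumulative_min: int = 2000
    test_lookaway_max: int = 1500
    use_lookaway_criteria: bool = True

    def __post_init__(self) -> None:
        if self.fam_cumulative_min <= 0 or self.test_lookaway_max <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class ParticipantRecord:
    """One participant: metadata plus per-trial scores.

    ``scores`` maps trial role (fam1/fam2/test) to :class:`TrialScore`;
    scores may be absent only for procedural-error participants.
    """

    participant: str
    site: str
    condition: str
    procedural_error: bool = False
    scores: Mapping[str, TrialScore] = field(default_factory=dict)

    def score(self, role: str) -> TrialScore:
        try:
            return self.scores[role]
        except KeyError:
            raise DataError(
                f"participant {self.participant!r} lacks a {role} trial score"
            ) from None


@dataclass(frozen=True)
class RawParticipant:
    """Participant metadata plus unscored fixation sequences.

    The bridge between ingest/simulation and scoring: scoring a
    RawParticipant under a given paradigm configuration (and period-of-
    interest variant) yields a :class:`ParticipantRecord`.
    """

    participant: str
    site: str
    condition: str
    procedural_error: bool = False
    sequences: Mapping[str, FixationSequence] = field(default_factory=dict)


def build_record(
    raw: RawParticipant,
    aois: AOISet,
    config: dict | None = None,
    period_of_interest: int | None = None,
    lookaway_merge_tolerance: int = 0,
) -> ParticipantRecord:
    """Score a raw participant's trials into a :class:`ParticipantRecord`."""
    scores: dict[str, TrialScore] = {}
    if not raw.procedural_error:
        for role in ("fam1", "fam2", "test"):
            if role not in raw.sequences:
                raise DataError(
                    f"participant {raw.participant!r} lacks a {role} trial"
                )
            timeline = build_timeline(
                role,
                raw.condition if role == "test" else None,
                config=config,
                period_of_interest=period_of_interest,
            )
            scores[role] = score_trial(
                raw.sequences[role], aois, timeline, lookaway_merge_tolerance
            )
    return ParticipantRecord(
        participant=raw.participant,
        site=raw.site,
        condition=raw.condition,
        procedural_error=raw.procedural_error,
        scores=scores,
    )


@dataclass(frozen=True)
class ExclusionLedger:
    """Cascade outcome: per-participant status and per-reason counts."""

    status: Mapping[str, str]  # participant -> "included" | "excluded"
    reason: Mapping[str, str]  # excluded participant -> reason
    site: Mapping[str, str]

    @property
    def n_total(self) -> int:
        return len(self.status)

    @property
    def n_included(self) -> int:
        return sum(1 for s in self.status.values() if s == "included")

    @property
    def n_excluded(self) -> int:
        return self.n_total - self.n_included

    def counts(self, site: str | None = None) -> dict[str, int]:
        """Per-reason exclusion counts, optionally for one site."""
        c = Counter(
            r
            for p, r in self.reason.items()
            if site is None or self.site[p] == site
        )
        return {reason: c.get(reason, 0) for reason in EXCLUSION_REASONS}

    def summary(self) -> dict:
        """JSON-ready counts by site and overall, mirroring the reporting
        format of per-site attrition ledgers."""
        sites = sorted(set(self.site.values()))
        out: dict = {"total": self.n_total, "included": self.n_included,
                     "excluded": self.n_excluded, "by_reason": self.counts(),
                     "by_site": {}}
        for s in sites:
            n_site = sum(1 for v in self.site.values() if v == s)
            inc = sum(
                1 for p, st in self.status.items()
                if st == "included" and self.site[p] == s
            )
            out["by_site"][s] = {
                "total": n_site,
                "included": inc,
                "excluded": n_site - inc,
                "by_reason": self.counts(s),
            }
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (p, self.site[p], st, self.reason.get(p, ""))
            for p, st in self.status.items()
        ]
        return pd.DataFrame(rows, columns=["participant", "site", "status", "reason"])


def _failure_reason(
    rec: ParticipantRecord, thresholds: ExclusionThresholds
) -> str | None:
    """First failing criterion in cascade order, or None if fully included."""
    if rec.procedural_error:
        return "procedural"
    if thresholds.use_lookaway_criteria:
        fam_coverage = (
            rec.score("fam1").cumulative_on_scene_in_key_periods
            + rec.score("fam2").cumulative_on_scene_in_key_periods
        )
        if fam_coverage < thresholds.fam_cumulative_min:
            return "fam_attention"
        if (
            rec.score("test").max_consecutive_lookaway_in_key_periods
            > thresholds.test_lookaway_max
        ):
            return "test_lookaway"
    if rec.score("test").first_look_side is Side.NONE:
        return "no_test_first_fixation"
    if not (rec.score("test").looked_during_cue and rec.score("fam2").looked_during_cue):
        return "missed_cue"
    if rec.score("fam2").first_look_side is not Side.RIGHT:
        return "fam2_incorrect"
    return None


def apply_exclusions(
    records: Sequence[ParticipantRecord],
    thresholds: ExclusionThresholds | None = None,
) -> tuple[list[ParticipantRecord], list[ParticipantRecord], ExclusionLedger]:
    """Run the cascade.

    Returns ``(main_sample, fam2_incorrect_sample, ledger)``.  The main
    sample passes every criterion; the fam2-incorrect sample passes all but
    the last and made an (incorrect) left-side first look in the second
    familiarization trial, for the follow-up condition x inclusion analysis.
    The outcome is a pure, order-insensitive function of the records.
    """
    thresholds = thresholds or ExclusionThresholds()
    main: list[ParticipantRecord] = []
    fam2_incorrect: list[ParticipantRecord] = []
    status: dict[str, str] = {}
    reason: dict[str, str] = {}
    site: dict[str, str] = {}
    for rec in records:
        if rec.participant in status:
            raise DataError(f"duplicate participant id {rec.participant!r}")
        site[rec.participant] = rec.site
        why = _failure_reason(rec, thresholds)
        if why is None:
            status[rec.participant] = "included"
            main.append(rec)
        else:
            status[rec.participant] = "excluded"
            reason[rec.participant] = why
            if why == "fam2_incorrect" and rec.score("fam2").first_look_side is Side.LEFT:
                fam2_incorrect.append(rec)
    return main, fam2_incorrect, ExclusionLedger(status, reason, site)


def measure_table(
    samples: Mapping[str, Sequence[ParticipantRecord]]
) -> pd.DataFrame:
    """Tidy analysis table: one row per participant.

    ``samples`` maps an inclusion stratum label (e.g. ``included`` /
    ``fam2_incorrect``) to its records.  Columns: participant, site,
    condition, inclusion stratum, test first-look side and correctness,
    DLS (NaN when undefined), correct/incorrect window-only ms, and the
    head-before-window flag.  Undefined-DLS participants keep their row;
    downstream analyses drop them explicitly.
    """
    rows = []
    for stratum, records in samples.items():
        for rec in records:
            ts = rec.score("test")
            d = ts.dls
            rows.append(
                {
                    "participant": rec.participant,
                    "site": rec.site,
                    "condition": rec.condition,
                    "inclusion": stratum,
                    "first_look_side": ts.first_look_side.value,
                    "first_look_correct": _first_look_correct(rec),
                    "dls": float("nan") if d is None else d,
                    "correct_window_ms": ts.correct_window_time,
                    "incorrect_window_ms": ts.incorrect_window_time,
                    "head_before_window": ts.first_window_fixation_after_head,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "participant", "site", "condition", "inclusion",
            "first_look_side", "first_look_correct", "dls",
            "correct_window_ms", "incorrect_window_ms", "head_before_window",
        ],
    )


def _first_look_correct(rec: ParticipantRecord) -> bool:
    from .paradigm import CORRECT_SIDES

    ts = rec.score("test")
    return ts.first_look_side is CORRECT_SIDES[("test", rec.condition)]
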