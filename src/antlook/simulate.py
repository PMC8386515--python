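"""Synthetic infant-gaze simulator.

Generates per-participant fixation sequences for the two familiarization
trials and the test trial, with controllable attention, anticipation
accuracy, first-look latency and side bias, so the full pipeline —
ingest, scoring, exclusion cascade, statistics — can be exercised end to
end, validated by parameter recovery, and used for attrition studies.

The behavioural model is deliberately minimal but can produce every
exclusion reason and both dependent measures:

* Each participant has a latent attentiveness ``theta`` drawn from a Beta
  distribution with mean ``p_attend``; each key period is attended with
  probability ``theta``.  Unattended key periods are blanked (gaze off
  scene for the whole period), which is what drives the familiarization
  attention and test look-away exclusions.  The audio-visual cue can
  capture a brief glance even in an unattended period (``cue_capture``),
  mirroring its attention-getting design.
* Outside key-period blanking, gaze alternates lognormal-duration
  fixations over the agent's head, the scene centre and (pre-cue) windows
  and boxes, with off-scene gaps started at ``lookaway_hazard`` per second
  of fixation.
* After cue onset, with probability ``p_first_look`` the participant makes
  an anticipatory saccade after a shifted-lognormal latency; its target
  side is correct with probability ``p_anticipate_*``, shifted by
  ``side_bias_right``; the landing point falls in the window (or, with
  probability ``p_box_landing``, on the box below).  Subsequent fixations
  follow a simple Markov dwell over {current window, other window, head},
  again biased by ``side_bias_right``, which is what gives the
  differential looking score its signal.

Generation is a pure function of ``(params, seed)``: participant
substreams are derived from the master seed by counter-based
``SeedSequence`` spawning, so cohorts are reproducible and participants
independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Sequence

import numpy as np

from .cohort import (
    ExclusionThresholds,
    ParticipantRecord,
    RawParticipant,
    apply_exclusions,
    build_record,
)
from .events import FixationEvent, FixationSequence
from .paradigm import (
    CONDITIONS,
    AOISet,
    Rect,
    Side,
    TrialTimeline,
    build_timeline,
    load_aois,
    load_paradigm_config,
)
from .stats import exact_binomial_two_tailed

SITES = ("CPH", "BP")


@dataclass(frozen=True)
class SimulationParams:
    """Generator settings.

    Defaults emulate the replication-study conditions: 40 infants per
    condition per site (160 total), a 54%-correct anticipation probability
    in the second familiarization trial and 45% on test with a small
    right-side bias, and attention parameters calibrated so the included
    main-analysis sample lands near n = 49.  Probabilities are in [0, 1];
    durations in ms.
    """

    n_per_condition_per_site: int = 40
    # attention
    p_attend: float = 0.84
    attend_concentration: float = 2.0
    lookaway_hazard: float = 0.3  # per second of fixation
    cue_capture: float = 0.95
    # anticipation
    p_anticipate_fam2: float = 0.54
    p_anticipate_test: float = 0.45
    side_bias_right: float = 0.05
    p_first_look: float = 0.97
    p_box_landing: float = 0.2
    # cohort
    p_procedural_error: float = 0.069
    # kinematics
    fixation_median_ms: float = 400.0
    fixation_sigma: float = 0.5
    gap_median_ms: float = 300.0
    gap_sigma: float = 0.6
    gap_max_ms: int = 1200
    latency_shift_ms: float = 300.0
    latency_median_ms: float = 600.0
    latency_sigma: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "p_attend", "cue_capture", "p_anticipate_fam2", "p_anticipate_test",
            "side_bias_right", "p_first_look", "p_box_landing",
            "p_procedural_error",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in (
            "fixation_median_ms", "gap_median_ms", "latency_median_ms",
            "latency_shift_ms", "attend_concentration",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_per_condition_per_site < 1:
            raise ValueError("n_per_condition_per_site must be >= 1")
        if self.lookaway_hazard < 0:
            raise ValueError("lookaway_hazard must be >= 0")


@lru_cache(maxsize=4)
def _default_setting() -> tuple[AOISet, dict]:
    cfg = load_paradigm_config()
    return load_aois(cfg), cfg


def _participant_rng(master_seed: int, index: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([master_seed, index])))


def _theta(rng: np.random.Generator, p: SimulationParams) -> float:
    if p.p_attend <= 0.0 or p.p_attend >= 1.0:
        return p.p_attend
    k = p.attend_concentration
    return float(rng.beta(k * p.p_attend, k * (1.0 - p.p_attend)))


def _point_in(rng: np.random.Generator, rect: Rect, margin: float = 0.02) -> tuple[float, float]:
    x = rng.uniform(rect.x0 + margin, rect.x1 - margin)
    y = rng.uniform(rect.y0 + margin, rect.y1 - margin)
    return float(x), float(y)


def _lognormal(rng: np.random.Generator, median: float, sigma: float) -> float:
    return float(median * math.exp(sigma * rng.standard_normal()))


def _gen_trial(
    rng: np.random.Generator,
    p: SimulationParams,
    timeline: TrialTimeline,
    aois: AOISet,
    theta: float,
    p_anticipate: float,
) -> list[FixationEvent]:
    """Generate one trial's fixation events (sorted, non-overlapping)."""
    cue_on, cue_off = timeline.cue_interval
    poi_start, poi_end = timeline.interest_interval
    duration = timeline.duration
    head_rect = aois.head
    wo = aois.window_only
    wb = aois.window_box

    makes_look = rng.random() < p.p_first_look
    a_on: int | None = None
    side = "right"
    if makes_look:
        latency = p.latency_shift_ms + _lognormal(
            rng, p.latency_median_ms, p.latency_sigma
        )
        # the look, when made, lands inside the period of interest: whether
        # any look occurs at all is governed by p_first_look alone
        a_on = cue_on + min(int(latency), timeline.period_of_interest - 100)
        base = p_anticipate if timeline.correct_side is Side.RIGHT else 1.0 - p_anticipate
        p_right = min(1.0, max(0.0, base + p.side_bias_right))
        side = "right" if rng.random() < p_right else "left"

    raw: list[tuple[int, int, float, float]] = []

    def wander(t: int, end: int) -> None:
        while t < end - 60:
            dur = int(min(max(_lognormal(rng, p.fixation_median_ms, p.fixation_sigma), 80), 1500))
            off = min(t + dur, end)
            u = rng.random()
            if poi_start <= t < poi_end or (a_on is not None and t >= cue_on):
                # anticipation is modelled explicitly; pre-saccade gaze
                # stays on the agent / scene centre
                x, y = _point_in(rng, head_rect) if u < 0.7 else _centre(rng)
            else:
                if u < 0.45:
                    x, y = _point_in(rng, head_rect)
                elif u < 0.75:
                    x, y = _centre(rng)
                elif u < 0.9:
                    x, y = _point_in(rng, wo[("left", "right")[rng.random() < 0.5]])
                else:
                    x, y = _box_point(rng, aois, ("left", "right")[rng.random() < 0.5])
            raw.append((t, off, x, y))
            t = off + _gap(rng, p, off - t)

    def _centre(r: np.random.Generator) -> tuple[float, float]:
        return float(r.uniform(0.42, 0.58)), float(r.uniform(0.58, 0.75))

    wander(0, a_on if a_on is not None else duration)

    if a_on is not None:
        dur = int(min(max(_lognormal(rng, 1.5 * p.fixation_median_ms, p.fixation_sigma), 120), 2000))
        a_off = min(a_on + dur, duration)
        if rng.random() < p.p_box_landing:
            x, y = _box_point(rng, aois, side)
        else:
            x, y = _point_in(rng, wo[side])
        raw.append((a_on, a_off, x, y))
        # Markov dwell over {current window, other window, head}
        t = a_off + _gap(rng, p, a_off - a_on)
        cur = side
        while t < duration - 60:
            dur = int(min(max(_lognormal(rng, p.fixation_median_ms, p.fixation_sigma), 80), 1500))
            off = min(t + dur, duration)
            w_same, w_other, w_head = 0.50, 0.22, 0.28
            weights = {cur: w_same, _other(cur): w_other}
            weights["right"] = max(0.01, weights["right"] + p.side_bias_right)
            weights["left"] = max(0.01, weights["left"] - p.side_bias_right)
            total = weights["left"] + weights["right"] + w_head
            u = rng.random() * total
            if u < weights["left"]:
                cur = "left"
                x, y = _point_in(rng, wo["left"])
            elif u < weights["left"] + weights["right"]:
                cur = "right"
                x, y = _point_in(rng, wo["right"])
            else:
                x, y = _point_in(rng, head_rect)
            raw.append((t, off, x, y))
            t = off + _gap(rng, p, off - t)

    # attention blanking: unattended key periods lose all fixation coverage
    attended = [rng.random() < theta for _ in timeline.key_periods]
    blanks = [kp for kp, a in zip(timeline.key_periods, attended) if not a]
    if blanks:
        raw = _subtract(raw, blanks)

    # the flashing cue can capture a glance even from an inattentive infant
    if not any(on < cue_off and off > cue_on for on, off, _, _ in raw):
        if rng.random() < p.cue_capture:
            x, y = _point_in(rng, head_rect)
            raw.append((cue_on + 100, cue_on + 300, x, y))
            raw.sort()

    return [FixationEvent(on, off, x, y) for on, off, x, y in raw if off > on]


def _other(side: str) -> str:
    return "left" if side == "right" else "right"


def _box_point(rng: np.random.Generator, aois: AOISet, side: str) -> tuple[float, float]:
    """A point in the box band: inside window_box but below the window."""
    outer, inner = aois.window_box[side], aois.window_only[side]
    x = float(rng.uniform(outer.x0 + 0.02, outer.x1 - 0.02))
    y = float(rng.uniform(inner.y1 + 0.02, outer.y1 - 0.02))
    return x, y


def _gap(rng: np.random.Generator, p: SimulationParams, fix_dur: int) -> int:
    """Inter-fixation interval: a saccade, or an off-scene look-away."""
    if p.lookaway_hazard > 0 and rng.random() < 1.0 - math.exp(
        -p.lookaway_hazard * fix_dur / 1000.0
    ):
        return int(min(max(_lognormal(rng, p.gap_median_ms, p.gap_sigma), 50), p.gap_max_ms))
    return 30


def _subtract(
    raw: list[tuple[int, int, float, float]], blanks: Sequence[tuple[int, int]]
) -> list[tuple[int, int, float, float]]:
    """Remove the parts of fixations that fall inside blanked periods."""
    out = []
    for on, off, x, y in raw:
        pieces = [(on, off)]
        for b0, b1 in blanks:
            nxt = []
            for a0, a1 in pieces:
                if a1 <= b0 or a0 >= b1:
                    nxt.append((a0, a1))
                else:
                    if a0 < b0:
                        nxt.append((a0, b0))
                    if a1 > b1:
                        nxt.append((b1, a1))
            pieces = nxt
        out.extend((a0, a1, x, y) for a0, a1 in pieces)
    return out


def simulate_participant_sequences(
    params: SimulationParams,
    condition: str,
    participant_seed: int,
    participant_id: str,
    site: str = "CPH",
    config: dict | None = None,
) -> RawParticipant:
    """Simulate one participant's three trials (or a procedural error)."""
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    aois, cfg = _default_setting() if config is None else (load_aois(config), config)
    rng = _participant_rng(params.seed, participant_seed)
    if rng.random() < params.p_procedural_error:
        return RawParticipant(participant_id, site, condition, procedural_error=True)
    theta = _theta(rng, params)
    sequences = {}
    for role in ("fam1", "fam2", "test"):
        timeline = build_timeline(role, condition if role == "test" else None, cfg)
        p_ant = params.p_anticipate_test if role == "test" else params.p_anticipate_fam2
        events = _gen_trial(rng, params, timeline, aois, theta, p_ant)
        sequences[role] = FixationSequence(participant_id, role, tuple(events))
    return RawParticipant(participant_id, site, condition, False, sequences)


def simulate_participant(
    params: SimulationParams,
    condition: str,
    participant_seed: int,
    participant_id: str | None = None,
    site: str = "CPH",
    config: dict | None = None,
) -> ParticipantRecord:
    """Simulate and score one participant under the paradigm defaults."""
    pid = participant_id or f"sim{participant_seed:04d}"
    raw = simulate_participant_sequences(params, condition, participant_seed, pid, site, config)
    aois, cfg = _default_setting() if config is None else (load_aois(config), config)
    return build_record(raw, aois, cfg)


def simulate_cohort(
    params: SimulationParams, config: dict | None = None
) -> list[RawParticipant]:
    """Simulate a full cohort, balanced over condition x site.

    With defaults: 40 participants per condition per site, 160 total.
    """
    out: list[RawParticipant] = []
    idx = 0
    for site in SITES:
        for condition in CONDITIONS:
            for _ in range(params.n_per_condition_per_site):
                pid = f"{site}-{condition}-{idx:04d}"
                out.append(
                    simulate_participant_sequences(
                        params, condition, idx, pid, site, config
                    )
                )
                idx += 1
    return out


@lru_cache(maxsize=256)
def binomial_test_size(n: int, alpha: float = 0.05, p0: float = 0.5) -> float:
    """Exact size of the two-tailed binomial test at sample size ``n``.

    The achieved type-I error rate: total null probability of all outcomes
    whose two-tailed exact p-value is at or below ``alpha``.  Discreteness
    makes this smaller than ``alpha`` for most ``n``.
    """
    from scipy.stats import binom

    pmf = binom.pmf(np.arange(n + 1), n, p0)
    size = 0.0
    for k in range(n + 1):
        if exact_binomial_two_tailed(k, n, p0).p <= alpha:
            size += float(pmf[k])
    return size


def recover_anticipation(
    params: SimulationParams,
    replicates: int,
    alpha: float = 0.05,
    thresholds: ExclusionThresholds | None = None,
) -> dict:
    """Parameter-recovery / test-size study over simulated cohorts.

    For each replicate: simulate a cohort, run the full pipeline (scoring
    plus exclusion cascade), estimate the included-sample correct-
    anticipation proportions for the second familiarization and the test
    trial, and run the two-tailed exact binomial test of the test-trial
    proportion against 0.5.  Reports estimate means and bias relative to
    the generating ``p_anticipate_test``, the empirical rejection rate,
    and the mean exact test size at the realized sample sizes (the correct
    null-rejection benchmark, since the exact test is conservative).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    aois, cfg = _default_setting()
    n_incl, fam2_prop, test_prop, pvals, sizes = [], [], [], [], []
    for r in range(replicates):
        sub = int(np.random.SeedSequence([params.seed, r]).generate_state(1)[0] & 0x7FFFFFFF)
        raws = simulate_cohort(replace(params, seed=sub), cfg)
        records = [build_record(raw, aois, cfg) for raw in raws]
        main, fam2_inc, ledger = apply_exclusions(records, thresholds)
        n = len(main)
        n_incl.append(n)
        n_pass_upstream = n + ledger.counts()["fam2_incorrect"]
        fam2_prop.append(n / n_pass_upstream if n_pass_upstream else math.nan)
        if n == 0:
            test_prop.append(math.nan)
            pvals.append(math.nan)
            sizes.append(math.nan)
            continue
        k = sum(
            1
            for rec in main
            if rec.score("test").first_look_side
            is build_timeline("test", rec.condition, cfg).correct_side
        )
        test_prop.append(k / n)
        pvals.append(exact_binomial_two_tailed(k, n, 0.5).p)
        sizes.append(binomial_test_size(n, alpha))
    pv = np.asarray(pvals)
    ok = np.isfinite(pv)
    return {
        "replicates": replicates,
        "alpha": alpha,
        "n_included": np.asarray(n_incl),
        "fam2_proportion": np.asarray(fam2_prop),
        "test_proportion": np.asarray(test_prop),
        "p_values": pv,
        "mean_n_included": float(np.mean(n_incl)),
        "mean_fam2_proportion": float(np.nanmean(fam2_prop)),
        "mean_test_proportion": float(np.nanmean(test_prop)),
        "bias_test": float(np.nanmean(test_prop) - params.p_anticipate_test),
        "rejection_rate": float(np.mean(pv[ok] <= alpha)) if ok.any() else math.nan,
        "expected_rejection_rate": float(np.nanmean(sizes)),
    }
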