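# Methods

## The measurement problem

Anticipatory-looking paradigms infer cognition from *where infants look
before an action happens*. The two-window false-belief task shows an agent
who will reach through one of two windows for a hidden ball; a 1 s
audio-visual cue announces the impending reach, and the dependent measures
are taken in the **period of interest** — the 2750 ms from cue onset, the
actual cue-to-reach lag in the familiarization videos (an alternative
1750 ms period, which has circulated in earlier reports of the paradigm, is
retained as an analysis variant). The belief-congruent ("correct") side is
fixed by the scenario: left in the first familiarization, right in the
second; right in test condition FB1 and left in FB2, where the agent's
belief about the ball's location is false.

All scoring is interval arithmetic over parsed *fixation events* (onset,
offset, landing point), the output of an eye-tracker's online event parser.
Saccades and blinks appear only as gaps between fixations; "looking away"
means absence of on-scene fixation coverage, with gaps and off-scene
fixations treated identically.

## Conventions

These choices are deliberate, echoed in every run report, and worth stating
because exactly such conventions drive disputes between nominally identical
analyses:

- **Time**: integer milliseconds, half-open intervals `[onset, offset)`. A
  fixation ending exactly at cue onset does not overlap the cue.
- **Coordinates**: normalized to the stimulus frame (origin top-left, y
  downward), so one AOI configuration serves monitors of different size.
  Normalized positions are clamped to [−0.5, 1.5]; off-scene looking is
  legitimate data.
- **AOI containment**: min-edge inclusive, max-edge exclusive, so abutting
  left/right AOIs never both claim a point. Window-only AOIs are nested in
  window+box AOIs by construction.
- **First look**: the first fixation whose *onset* falls in the period of
  interest and whose *landing point* lies in a window+box AOI. A fixation
  already ongoing at cue onset is not a new orientation and does not count;
  the saccade path is not reconstructed. Window+box (rather than
  window-only) AOIs approximate manual coding traditions that credited gaze
  passing through a window toward the box below.
- **DLS**: window-only AOIs, fixation time clipped at the period
  boundaries (partial credit for the in-period fraction); undefined when
  neither window was fixated, and undefined scores are excluded listwise
  from *t*-tests and ANOVA, never imputed.
- **Look-away**: longest sub-interval of a single key period uncovered by
  on-scene fixations; gaps never bridge distinct key periods. A configurable
  merge tolerance (default 0 ms — strict, since no blink forgiveness is part
  of the preregistered definitions) can forgive short gaps.
- **Cascade precedence**: exclusion reasons are attributed
  first-failing-criterion in the preregistered listing order (procedural →
  fam inattention → test look-away → no test fixation → missed cue → fam2
  incorrect). Reported counts are therefore mutually exclusive and
  reconcile exactly with the cohort size.
- **Exact tests**: point-probability two-tailed convention — the two-sided
  p is the total probability of outcomes no more likely than the one
  observed (the convention of scipy and R's `binom.test`/`fisher.test`).
- **ANOVA**: Type-III sums of squares with sum-to-zero contrasts, matching
  the SPSS-style reporting tradition for unbalanced designs. Other SS types
  are intentionally not offered.

## Statistical battery

Exact binomial and Fisher tests, one-sample *t* (df = n−1) and Welch *t*
(Satterthwaite fractional df) are computed via scipy behind the package's
interfaces; the 2×2 between-subjects ANOVA via statsmodels OLS with
Type-III decomposition. The 2×2 mixed ANOVA on looking durations
(window: correct/incorrect within; condition between) is implemented
through the exact algebraic equivalence available when the within factor
has two levels: the between effect is the condition effect on
per-participant means, while the within effect and interaction are the
intercept and slope tests of the difference scores, sharing the
subject × window error term (df = N − 2). Under imbalance the within
effect tests the *unweighted* (Type III) grand mean of the difference
scores, consistent with the package-wide convention; textbook
weighted-marginal formulas differ in that case. The test suite
cross-checks balanced designs against pingouin's independent mixed-ANOVA
implementation and exact-fraction enumeration oracles for both exact
tests.

## Paradigm geometry and timing defaults

The AOI rectangles and key-period anchors are measured properties of the
stimulus videos. The defaults shipped in `antlook/data/default_paradigm.json`
are **documented placeholders** — left/right halves of the frame with
windows in an upper band, boxes below them, the agent's head top-centre;
key periods anchored to the ball-hiding events and the cue-to-reach span
(familiarization: 2–6 s and 8–12.75 s of a 16 s trial, cue at 8 s; test:
2–12 s and 14–16.75 s of a 22 s trial, cue at 14 s). Every rectangle and
anchor is overridable by a user JSON file of the same schema, and analyses
of real recordings should override them with values measured from the
stimuli. Exclusion thresholds default to the preregistered 2000 ms
cumulative familiarization attention and 1500 ms consecutive test
look-away.

## The synthetic gaze generator

The simulator produces the full three-trial record for cohorts balanced
over two sites × two conditions (default 40 per cell, 160 infants). Its
behavioural model is the minimal one that can produce every exclusion
reason and both dependent measures:

- **Attention.** Each participant draws a latent attentiveness θ from a
  Beta distribution with mean `p_attend` (default 0.84) and concentration 2
  (infants vary a lot); each key period is independently attended with
  probability θ. Unattended periods are blanked — gaze is off-scene
  throughout — which drives the familiarization-attention and test
  look-away exclusions. The flashing cue can capture a brief glance even
  during an unattended period (`cue_capture` = 0.95), mirroring its
  attention-getting purpose; this keeps missed-cue exclusions rare, as in
  real cohorts.
- **Baseline gaze.** Lognormal fixation durations (median 400 ms, σ 0.5)
  over the agent's head, scene centre and — outside the period of
  interest — windows and boxes, with off-scene gaps initiated at
  `lookaway_hazard` 0.3 per second of fixation (lognormal gap durations,
  median 300 ms, capped at 1.2 s so that look-away exclusions are governed
  by the attention model, not the gap tail).
- **Anticipation.** With probability `p_first_look` (0.97) the participant
  makes an anticipatory saccade after a shifted-lognormal latency
  (300 + LN(600 ms, σ 0.6), clipped into the period); its side is correct
  with probability `p_anticipate_fam2` / `p_anticipate_test`, shifted
  toward the right by `side_bias_right`; the landing point falls in the
  window, or with probability 0.2 on the box below (exercising the
  window+box vs window-only distinction, including the rare
  box-but-never-window participant whose DLS is undefined). Subsequent
  fixations follow a Markov dwell over {current window, other window,
  head}, again right-biased, which gives the DLS its signal.
- **Seeding.** Participant substreams derive from the master seed by
  counter-based `SeedSequence` spawning: cohorts are reproducible,
  participants independent, and generation is a pure function of
  (parameters, seed).

Default behavioural parameters are the study conditions the pipeline is
meant to operate under: `p_anticipate_fam2` = 0.54 and `p_anticipate_test`
= 0.45 (the reported anticipation rates), `side_bias_right` = 0.05 (the
reported right-side tendency), procedural errors at 0.069. Attention
blanking attenuates the *realized* fam2-correct proportion below the
generative 0.54 (an infant who ignores the fam2 cue period contributes no
first look), so `p_attend` was calibrated to 0.84 to place the included
main-analysis sample near n = 49, the size at which the pipeline's
operating characteristics are studied; the corresponding total attrition is
somewhat lower than in the real study. With these defaults a cohort of 160
yields roughly 50 included infants.

What the simulator does *not* emulate: saccade kinematics and
path-dependent AOI entry, pupil and blink physiology, drift and
calibration error, site differences, age effects, and any coupling between
attention and anticipation ability (θ and the anticipation draws are
independent). Passing recovery tests therefore show that the pipeline
measures what the generative model encodes — not that the generative model
captures real infant gaze.

## Validation strategy

- Interval algebra (coverage, longest gap, window times) is checked
  against a brute-force 1 ms-grid oracle on hundreds of randomized
  sequences; coverage + uncovered time must conserve total key-period
  duration exactly.
- Both exact tests are checked against exact-fraction full-enumeration
  oracles for every input with n ≤ 12 (binomial) and every 2×2 table with
  N ≤ 12 (Fisher), and against published worked examples (p = 0.568 for
  22/49; p = 0.565 for [[15,16],[7,11]]).
- Degrees-of-freedom conventions are pinned by fixtures shaped to the
  published reports (one-sample df 47 from 49 scores with one undefined;
  ANOVA error df 85 from 90 with one undefined).
- Parameter recovery: at `p_anticipate_test` = 0.5 with no bias, the exact
  binomial test's rejection rate over 1000 simulated cohorts matches the
  test's exact (sub-nominal) size at the realized included-sample sizes;
  at 0.9 the mean pipeline estimate recovers the generating value. The
  acceptance script reruns a reduced version of this study.

## Known limitations

- The shipped AOI/key-period geometry is a placeholder; results on real
  recordings are only as good as the measured geometry supplied.
- ASC ingestion covers EFIX event lines with configurable trial markers;
  raw-sample parsing and fixation detection are out of scope (use the
  vendor parser or an offline detector upstream).
- The mixed ANOVA is specialized to a two-level within factor; more
  window conditions would need a general repeated-measures implementation.
- The cascade assumes one record per participant and complete trial
  scores for non-procedural participants; partial records are rejected
  rather than silently imputed.
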