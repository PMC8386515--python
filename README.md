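# antlook

Analysis pipeline for infant **anticipatory-looking** eye-tracking studies of
the two-window / two-box false-belief paradigm, built for developmental
researchers who want a preregistered-style exclusion cascade and dependent
measures implemented as tested, auditable code rather than ad-hoc scripts.

In this paradigm an agent watches a puppet hide a ball under one of two
windows; after an audio-visual cue, the agent reaches through a window. In
the false-belief test trials the agent's *belief* about the ball's location
is outdated, so the belief-congruent window (right in condition FB1, left in
FB2) differs from the ball's true location. Whether infants look at the
belief-congruent window *before* the reach is read as an index of
false-belief attribution.

## What it computes

From per-participant fixation events (EyeLink-ASC-style event files or a
tidy CSV dialect), for each trial:

- **attention metrics** over preregistered key periods: cumulative on-scene
  fixation time and the longest consecutive look-away;
- the binary **first look**: the side of the first window+box AOI fixated
  within the period of interest (2750 ms from cue onset; a 1750 ms variant
  is available), using the fixation onset and landing point;
- the **differential looking score**

  `DLS = t_correct / (t_correct + t_incorrect)`,

  where `t_side` is the cumulative fixation time on the window-only AOI of
  each side within the period of interest (0.5 is chance; undefined when
  neither window was fixated).

Participants then pass through the exclusion cascade — procedural error,
familiarization inattention (< 2 s cumulative), test look-away (> 1.5 s
consecutive), no test first fixation, missed cue, incorrect fam2
anticipation — each exclusion attributed to the *first* criterion failed.
The statistical battery covers the two-tailed exact binomial test
(point-probability convention), Fisher's exact test, one-sample and Welch
*t*-tests, a Type-III 2×2 between-subjects ANOVA, and a 2×2 mixed ANOVA on
looking durations. A synthetic infant-gaze simulator generates full cohorts
with controllable attention, anticipation accuracy and side bias, so the
entire pipeline is testable end to end and supports parameter-recovery and
attrition studies.

## Worked example

The exact tests need only published summary counts (22 of 49 infants
anticipating correctly overall; 15 of 31 in FB1 vs 7 of 18 in FB2):

```python
from antlook import exact_binomial_two_tailed, fisher_exact_two_tailed

binom = exact_binomial_two_tailed(22, 49, 0.5)
fisher = fisher_exact_two_tailed([[15, 16], [7, 11]])
print(f"binomial p = {binom.p:.3f}, Fisher p = {fisher.p:.3f}")
```

```
binomial p = 0.568, Fisher p = 0.565
```

Neither test rejects chance: no evidence that first looks favour the
belief-congruent window, nor that the conditions differ. The `examples/`
directory has one short script per capability (parsing, trial scoring, the
exclusion cascade, the statistical battery, simulation + recovery); each
prints its results with a line of interpretation. For shell use there is a
thin CLI:

```sh
antlook simulate --seed 4 --out data/        # synthetic cohort as tidy CSV
antlook run --fixations data/fixations.csv \
            --participants data/participants.csv --out results/
antlook recover --replicates 200 --seed 1    # parameter-recovery study
```

`antlook run` writes a deterministic JSON report (exclusion ledger by site,
anticipation counts and tests, DLS descriptives and tests, the
condition × inclusion ANOVA), a human-readable rendering, per-participant
measure tables, and DLS figures. Supplementary-analysis variants are flags
(`--period-1750`, `--no-lookaway-criteria`, `--require-head-first`,
`--duration-anova`).

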