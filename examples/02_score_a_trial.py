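"""Score one test trial: attention, first look and DLS.

Builds a hand-written fixation sequence for an FB1 test trial (the
belief-congruent window is on the right) and prints every derived
measure.  With the shipped timeline the cue starts at 14 s and the
period of interest spans the following 2750 ms.
"""

from antlook import (
    FixationEvent,
    FixationSequence,
    build_timeline,
    load_aois,
    score_trial,
)

aois = load_aois()
timeline = build_timeline("test", "FB1")
print(f"cue at {timeline.cue_onset} ms, period of interest "
      f"{timeline.interest_interval}, correct side: {timeline.correct_side.value}")

head = aois.head.centre()
right_window = aois.window_only["right"].centre()
left_window = aois.window_only["left"].centre()

seq = FixationSequence(
    "infant01", "test",
    (
        FixationEvent(1000, 13500, *head),          # watching the actors
        FixationEvent(14100, 14900, *head),         # on the agent during the cue
        FixationEvent(15000, 15900, *right_window), # anticipatory look (correct)
        FixationEvent(16000, 16300, *left_window),  # brief check of the other side
        FixationEvent(16400, 20000, *head),
    ),
)

score = score_trial(seq, aois, timeline)
print(f"on-scene in key periods: {score.cumulative_on_scene_in_key_periods} ms")
print(f"longest look-away:       {score.max_consecutive_lookaway_in_key_periods} ms")
print(f"looked during cue:       {score.looked_during_cue}")
print(f"first look side:         {score.first_look_side.value}")
print(f"head before window:      {score.first_window_fixation_after_head}")
print(f"window times (correct/incorrect): {score.correct_window_time}/"
      f"{score.incorrect_window_time} ms -> DLS = {score.dls:.3f}")
print("A DLS above 0.5 means longer looking at the belief-congruent window.")
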