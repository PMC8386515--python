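{
  "schema_version": 1,
  "comment": "Placeholder paradigm geometry and timing. AOI rectangles are [x0, y0, x1, y1] in stimulus-proportion coordinates (origin top-left, y downward); times are ms from trial start. The true stimulus-video AOI pixel geometry and key-period anchors are properties of the stimulus movies and should be overridden with measured values when available; these defaults split the frame into left/right halves with windows in the upper band, boxes in the lower band and the agent's head top-centre, and anchor key periods to the ball-hiding events and the cue-to-reach span.",
  "aois": {
    "scene": [0.0, 0.0, 1.0, 1.0],
    "head": [0.40, 0.05, 0.60, 0.30],
    "window_only": {
      "left": [0.08, 0.30, 0.38, 0.55],
      "right": [0.62, 0.30, 0.92, 0.55]
    },
    "window_box": {
      "left": [0.08, 0.30, 0.38, 0.90],
      "right": [0.62, 0.30, 0.92, 0.90]
    }
  },
  "timelines": {
    "fam1": {
      "duration": 16000,
      "cue_onset": 8000,
      "cue_duration": 1000,
      "period_of_interest": 2750,
      "key_periods": [[2000, 6000], [8000, 12750]]
    },
    "fam2": {
      "duration": 16000,
      "cue_onset": 8000,
      "cue_duration": 1000,
      "period_of_interest": 2750,
      "key_periods": [[2000, 6000], [8000, 12750]]
    },
    "test": {
      "duration": 22000,
      "cue_onset": 14000,
      "cue_duration": 1000,
      "period_of_interest": 2750,
      "key_periods": [[2000, 12000], [14000, 16750]]
    }
  }
}
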