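"""Parse EyeLink-style fixation events and normalize to stimulus coordinates.

Fixation events arrive as EFIX lines between trial markers; times are
rebased to trial start and pixel landing points are mapped to
stimulus-proportion coordinates so one AOI configuration serves any
monitor size.
"""

from antlook import MarkerSpec, ScreenSpec, normalize_coordinates, read_asc_fixations

ASC = """\
MSG 122000 TRIAL_START fam1
EFIX R 122400 122800 400 640.0 512.0 900
EFIX R 122900 123350 450 260.0 420.0 900
MSG 138000 TRIAL_END
"""

# a 1280x1024 display with a centred 1000x800 stimulus frame
screen = ScreenSpec(width_px=1280, height_px=1024, stimulus_rect=(140, 112, 1000, 800))

(seq,) = read_asc_fixations(ASC, participant="infant01", markers=MarkerSpec())
norm = normalize_coordinates(seq, screen)

print(f"trial {norm.trial_role}: {len(norm.events)} fixations, "
      f"{norm.total_duration()} ms of fixation")
for ev in norm.events:
    print(f"  [{ev.onset:5d}, {ev.offset:5d}) ms  at ({ev.x:.3f}, {ev.y:.3f})")
print("Times are ms from trial start; (0.5, 0.5) is the stimulus-frame centre.")
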