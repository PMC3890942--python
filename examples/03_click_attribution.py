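"""Attribute clicks to their intended targets.

The rule samples relative positions one second before the click: the
partner's avatar wins if within +-70 units, else the partner's shadow,
else the player's own static object, else nothing.  Because the shadow
rides 150 units from the avatar, avatar and shadow can never both be in
range.
"""

import numpy as np

from percross import EnvConfig, TrialRecording, assign_click_target

cfg = EnvConfig()
n = 300


def fixed_recording(me, partner, static_me):
    pos = np.tile(np.array([[me], [partner]], dtype=float), (1, n))
    return TrialRecording(cfg=cfg, pos=pos, static_pos=np.array([static_me, 0.0]), clicks=[])


cases = [
    ("partner avatar 50 units away", fixed_recording(100.0, 150.0, 400.0)),
    ("partner 200 away, its shadow 50 away", fixed_recording(200.0, 0.0, 400.0)),
    ("only own static within range", fixed_recording(100.0, 300.0, 160.0)),
    ("nothing within 70 units", fixed_recording(100.0, 300.0, 500.0)),
]
for label, rec in cases:
    target = assign_click_target(rec, player=0, click_step=150)
    print(f"{label:<40} -> {target}")
# Only a click near the partner's avatar counts as correct in the
# tournament; shadow/static/none clicks cost the team a point.
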