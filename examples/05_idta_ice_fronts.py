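"""Infrared differential thermal analysis of a synthetic frame stack.

Generates an IR stack in which five leaf regions cool toward -14 units
and freeze one after another, detects per-region nucleation by frame
subtraction, and reports how fast the ice front covers each leaf.
"""

import numpy as np

from cryoleaf import coverage_curve, detect_region_events
from cryoleaf.synthetic import simulate_idta_stack

stack, masks, truth = simulate_idta_stack(5, 150, [20, 45, 70, 95, 120], seed=3)
events = detect_region_events(stack, threshold=1.0)

print("region  true frame  detected frame  full coverage after")
for t, e in zip(truth, events):
    curve = coverage_curve(stack, e, threshold=1.0)
    full = int(np.argmax(curve >= 0.95)) - e.frame_index
    print(f"{e.region_id:>6}  {t.frame_index:>10}  {e.frame_index:>14}  {full:>6} frames")
print()
print("Latent heat makes freezing tissue warmer than its previous frame, so")
print("frame subtraction turns the advancing ice front into a bright")
print("transient: brindled at onset, homogeneous within a few frames, and")
print("exactly one freezing event per leaf however far cooling continues.")
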