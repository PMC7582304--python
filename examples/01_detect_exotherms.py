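"""Detect freezing exotherms in a synthetic thermocouple campaign.

Simulates 5 nights of leaf/air/soil temperature logging (2 s sampling),
runs the ΔT = T(t) − T(t−10 s) detector, and compares the detected
events with the generator's ground truth.
"""

import numpy as np

from cryoleaf import DetectorParams, detect_exotherms, freeze_durations
from cryoleaf.synthetic import CampaignConfig, simulate_campaign

table, truth = simulate_campaign(CampaignConfig(n_nights=5, seed=42))
events = [freeze_durations(e, table) for e in detect_exotherms(table, DetectorParams())]

print(f"true freezing events injected : {len(truth.events)}")
print(f"events detected               : {len(events)}")
temps = [e.T_nucleation for e in events]
print(f"mean nucleation temperature   : {np.mean(temps):.2f} degC (generator: -2.6)")
frozen = [e.duration_frozen_min for e in events if e.duration_frozen_min is not None]
print(f"mean frozen duration          : {np.mean(frozen):.0f} min")
print()
print("Each event is the first 10 s window in which a leaf below 0 degC")
print("warmed by >= 0.5 degC - the latent-heat signature of ice nucleation;")
print("the nucleation temperature is the leaf temperature just before it.")
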