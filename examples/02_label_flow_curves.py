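"""Classify uroflow curve morphologies with the explicit rule cascade.

The labeler stands in for a physician's visual read: intermittent (pauses)
beats sawtooth (deep dips) beats tall-peak (fast high peak) beats flattened
(low plateau) beats the normal/decreased split at Qmax = 15 mL/s.
"""

import numpy as np

from vibrouroflow import FlowCurve, PatternLabel, classify_pattern
from vibrouroflow.synthetic import bell_curve

print("smooth bells around the 15 mL/s normal-flow rule:")
for q in (10.0, 14.9, 15.0, 22.0):
    lab = classify_pattern(bell_curve(q, duration=18.0, a=6.0, b=6.0))
    print(f"  Qmax {q:5.1f} mL/s -> label {int(lab)} ({lab.name})")

# carve a 2 s pause into a bell: the same curve becomes intermittent
c = bell_curve(22.0, duration=20.0)
flow = c.flow.copy()
mid = flow.size // 2
flow[mid:mid + int(2.0 / c.dt)] = 0.0
lab = classify_pattern(FlowCurve(dt=c.dt, flow=flow))
print(f"\nsame 22 mL/s bell with a 2 s mid-void pause -> label {int(lab)} "
      f"({lab.name})")
assert lab == PatternLabel.INTERMITTENT
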