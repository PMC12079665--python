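"""Build the three stimulus protocols and inspect their structure.

Ramp-and-hold stimuli decouple angular velocity (the ramp slope) from
angular position (the hold level); the stair probes history dependence by
visiting the same levels from both directions.
"""

import numpy as np

from joencode import ProtocolSpec, make_ramp_hold, make_stair

spec = ProtocolSpec(kind="variable_position", hold_positions_deg=(-1.0,),
                    ramp_velocity_deg_s=1.0)
trace = make_ramp_hold(spec)
print("ramp-and-hold to -1 deg at 1 deg/s:")
for ph in trace.phases:
    t0, t1 = trace.phase_window_s(ph)
    print(f"  {ph.label:5s} {ph.direction:7s} {t0:6.2f} -> {t1:6.2f} s")
# The ventral ramp lasts |Δθ|/v = 1 s; the hold 4 s.

stair = make_stair(ProtocolSpec.stair())
holds = stair.holds()
levels = [float(np.median(stair.position_deg[h.start:h.stop])) for h in holds]
print(f"\nstair: {len(holds)} holds over {stair.duration_s:.0f} s; levels visited:")
print("  " + " ".join(f"{l:+.1f}" for l in levels))
# Each 0.4-deg transition at 0.04 deg/s lasts 10 s; each hold 4 s.  The
# sequence descends to the most ventral level, ascends to the most dorsal,
# and returns, so interior levels are seen once per traversal direction.
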