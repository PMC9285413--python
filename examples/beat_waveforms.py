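"""Export the converged baseline beat as CSV and print beat-level events.

The waveform file carries one row per sample and one column per signal
(`<element>.<signal>`): chamber pressures/volumes/radii, valve flows and
opening fractions, and all compartment pressures.
"""

import numpy as np

from gravicor import study

baseline = study.calibrate_baseline()
beat = baseline.beat
beat.to_csv("npc_beat.csv")

q_av = beat.valve_flow("AV")
print(f"wrote npc_beat.csv ({len(beat.time)} samples over {beat.period:.3f} s)")
print(f"peak aortic flow      {q_av.max():6.1f} ml/s")
print(f"semilunar backflow    {q_av.min():6.1f} ml/s (closure spike)")
print(f"peak LV pressure      {beat.chamber_pressure('LV').max():6.1f} mmHg")
print(f"peak RV pressure      {beat.chamber_pressure('RV').max():6.1f} mmHg "
      "(about one sixth of the left side)")
print(f"LV volume range       {beat.chamber_volume('LV').min():5.1f}-"
      f"{beat.chamber_volume('LV').max():5.1f} ml")
print(f"mitral E/A double peak present: "
      f"{len(np.nonzero(np.diff(np.sign(np.diff(beat.valve_flow('MV')))) < 0)[0]) >= 2}")
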