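# Gestational stage targets.
#
# flow_pct: percentage of cardiac output to each systemic organ bed (each
# column sums to 100).  weight/height/HR/CO/perfusion pressure describe the
# representative woman at the non-pregnant baseline (NPC), the three
# trimesters (T1-T3) and the end of pregnancy (Term).
#
# valve_area_scale: multiplicative valve-area increase vs NPC.  Quantitative
# clinical data are scarce; the +5/+8/+10/+10% progression is an assumption
# (free configuration).  The tricuspid scale is always derived from the rule
# tv = mv * pv / av.

tau_sys_s: 0.81   # systemic RC time constant, held constant across stages
tau_pul_s: 0.5    # pulmonary RC time constant, held constant across stages

NPC:
  weight_kg: 56
  height_cm: 167
  hr_bpm: 71
  co_lmin: 4.9
  perfusion_pressure_mmhg: 76
  flow_pct: {liver: 6.56, gut: 26.0, upper_body: 22.0, kidneys: 21.0,
             uterus: 0.44, lower_body: 24.0}
  valve_area_scale: {MV: 1.0, AV: 1.0, PV: 1.0}

T1:
  weight_kg: 62
  height_cm: 165
  hr_bpm: 75
  co_lmin: 5.7
  perfusion_pressure_mmhg: 70
  flow_pct: {liver: 5.64, gut: 32.36, upper_body: 18.91, kidneys: 24.0,
             uterus: 4.17, lower_body: 14.92}
  valve_area_scale: {MV: 1.05, AV: 1.05, PV: 1.05}

T2:
  weight_kg: 65
  height_cm: 165
  hr_bpm: 76
  co_lmin: 5.9
  perfusion_pressure_mmhg: 72
  flow_pct: {liver: 5.45, gut: 34.55, upper_body: 18.27, kidneys: 23.0,
             uterus: 5.60, lower_body: 13.13}
  valve_area_scale: {MV: 1.08, AV: 1.08, PV: 1.08}

T3:
  weight_kg: 70
  height_cm: 165
  hr_bpm: 82
  co_lmin: 6.4
  perfusion_pressure_mmhg: 76
  flow_pct: {liver: 5.02, gut: 34.98, upper_body: 16.84, kidneys: 21.0,
             uterus: 10.88, lower_body: 11.28}
  valve_area_scale: {MV: 1.10, AV: 1.10, PV: 1.10}

Term:
  weight_kg: 75
  height_cm: 166
  hr_bpm: 79    # as reported: slightly below the T3 value
  co_lmin: 6.8
  perfusion_pressure_mmhg: 76
  flow_pct: {liver: 4.73, gut: 34.27, upper_body: 15.85, kidneys: 18.0,
             uterus: 15.0, lower_body: 12.15}
  valve_area_scale: {MV: 1.10, AV: 1.10, PV: 1.10}
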