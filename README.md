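# gravicor

Closed-loop lumped-parameter (0D) model of the maternal circulation with a
stress-homeostasis cardiac remodeling loop, for simulating the
cardiovascular adaptation to pregnancy.

## The problem

Healthy pregnancy is a sustained volume-overload state: cardiac output
rises by ~40%, systemic vascular resistance falls, blood volume expands,
and the heart remodels eccentrically — chambers dilate and their walls
thicken with a nearly constant relative wall thickness.  `gravicor` asks
how much of that structural remodeling follows from two simple homeostatic
principles, with no hormonal signalling: each chamber grows wall until its
myofiber stress σ_f returns to the non-pregnant set-point, and dilates
until its endocardial wall shear stress σ_wss does the same.

The package is for computational physiologists who want a fast, fully
scriptable whole-circulation model of pregnancy: every parameter is
configuration, every run is deterministic, and a complete gestational stage
converges in under a minute on one CPU.

## Model core

The circulation is a single closed loop (four elastance chambers, four
dynamic valves, aorta, six systemic organ beds, venae cavae, pulmonary
arteries and veins).  Chambers obey `p = E(t)(V − V_{p0})` with a
double-Hill `E(t)`; valves follow a Bernoulli law with blood inertance and
a pressure-driven opening fraction; organ beds are R_art–C_art–R_vb–C_ven–R_ven
compartments generated from stage targets:

    R_tot = PerfP / (%CO · CO),  split 5/92/3,
    C_art = τ_sys / R_vb,  C_ven = 30 C_art            (τ_sys = 0.81 s)

Cardiac remodeling runs one update per simulated heartbeat (2% tolerance):

    errCO    = (CO* − CO)/CO*      →  all volume/flow states × (1 + 0.01·errCO)
    errσ_f   = (σ_f − σ_f*)/σ_f*   →  v_wall += 0.005·errσ_f·σ_f*,  E_max, E_min ∝ v_wall
    errσ_wss = (σ_wss − σ_wss*)/σ_wss*  →  V_p0 += 1000·errσ_wss·σ_wss*

with σ_f the end-systolic meridional stress `P_es·r/(2h(1+h/2r))` for the
ventricles and the beat-mean thin-wall Laplace stress `P·r/(2h)` for the
atria, and `σ_wss = 4μ q/(π r̄³)`.  The starred targets are the converged
non-pregnant values.  The controlled variant (CRA) applies all three rules;
the uncontrolled variant (NCRA) applies only the blood-volume rule.

## Worked example

```python
from gravicor import study

base = study.calibrate_baseline()          # non-pregnant woman, CO -> 4.9 L/min
term = study.run_stage("Term", "CRA", base)

n, m = base.report.metrics, term.report.metrics
print(round(n["SV_ml"], 1), round(n["EF_pct"], 1), round(n["MAP_mmHg"], 1),
      round(n["SVR_dyn_s_cm5"]), round(n["LVM_g"], 1))
print(round(m["LVM_g"], 1), round(100*(m["LVM_g"]/n["LVM_g"] - 1), 1),
      round(100*(m["LVEDD_cm"]/n["LVEDD_cm"] - 1), 1), round(m["VTOTS_l"], 2))
```

prints

```
69.2 66.1 81.3 1294 88.0
131.7 49.7 10.3 2.05
```

Line 1 is the calibrated baseline panel: stroke volume 69.2 ml, ejection
fraction 66.1%, mean arterial pressure 81.3 mmHg, systemic vascular
resistance 1294 dyn·s/cm⁵, LV mass 88.0 g — the reference female
hemodynamics.  Line 2 is the controlled remodeling prediction at the end
of pregnancy: the LV grows to 131.7 g (+49.7%), its end-diastolic diameter
widens by 10.3%, and the stressed blood volume rises from 1.20 to 2.05 L,
the eccentric-hypertrophy pattern of normal gestation (see
`docs/methods.md` for where the predicted mass growth sits relative to the
reference trajectory, and why).

The `examples/` scripts cover the other capabilities (baseline panel, CRA
vs NCRA comparison, waveform export, stress-target sensitivity), and a thin
CLI mirrors them:

```bash
gravicor run --stage Term --mode CRA --out out/
gravicor reproduce-tables --out out/
gravicor scan-targets --stage T1 --out out/
```

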