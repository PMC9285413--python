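# Woman-specific baseline model configuration.
#
# Units: mmHg, ml, s; valve areas cm^2; blood density g/ml; viscosity poise.
#
# The chamber elastance constants, valve rate coefficients and great-vessel
# R/C values below are assumptions calibrated so that the non-pregnant
# baseline reproduces the reference female hemodynamics (CO 4.9 L/min,
# MAP ~82 mmHg, SV ~69 ml, EF ~66%, 6:1 LV:RV pressure ratio, stressed
# volume ~1.2 L).  They are free configuration, never hard-coded.

blood:
  mu_poise: 0.035     # dynamic viscosity (assumption; 3.5 cP)
  rho: 1.06           # blood density

pulmonary:
  perfusion_pressure_mmhg: 5.5   # mean PA-to-PV drop used to derive pulmonary R/C

myocardium:
  total_vmyo_ml: 109.0
  density_g_ml: 1.04
  distribution_mode: explicit    # stiffness/contractility-weighted shares;
  # the thin right-atrial share keeps the atrial thin-wall condition
  # (h/r < 0.1) satisfied across all gestational stages
  fractions: {LV: 0.776, RV: 0.154, LA: 0.045, RA: 0.025}

chambers:
  # double-Hill activation: tau1/tau2 contraction/relaxation time constants,
  # m1/m2 steepness; atrial onset is negative (late-beat activation, wrapped)
  LV: {Emax: 3.6,  Emin: 0.085, tau1: 0.215, tau2: 0.362, m1: 1.32, m2: 27.4,
       t_onset: 0.0,   Vp0: 8.5,  shape: half_ellipsoid}
  RV: {Emax: 0.50, Emin: 0.022, tau1: 0.215, tau2: 0.362, m1: 1.32, m2: 27.4,
       t_onset: 0.0,   Vp0: 10.0, shape: quarter_ellipsoid}
  LA: {Emax: 0.25, Emin: 0.15,  tau1: 0.11,  tau2: 0.18,  m1: 2.4,  m2: 15.0,
       t_onset: -0.17, Vp0: 3.0,  shape: sphere}
  RA: {Emax: 0.16, Emin: 0.06,  tau1: 0.11,  tau2: 0.18,  m1: 2.4,  m2: 15.0,
       t_onset: -0.17, Vp0: 5.0,  shape: sphere}

valves:
  # A_closed is the leak area (also the numerical floor); K are the
  # opening/closing rate coefficients of the pressure-driven dynamics
  AV: {A_open: 3.0, A_closed: 1.0e-4, K_open: 50.0, K_close: 40.0, l_eff: 1.5}
  PV: {A_open: 3.4, A_closed: 1.0e-4, K_open: 50.0, K_close: 40.0, l_eff: 1.5}
  MV: {A_open: 4.6, A_closed: 1.0e-4, K_open: 50.0, K_close: 40.0, l_eff: 1.5}
  TV: {A_open: 5.4, A_closed: 1.0e-4, K_open: 50.0, K_close: 40.0, l_eff: 1.5}

vessels:
  # aorta/pulm_art R: characteristic resistance in the upstream valve branch;
  # vena_cava/pulm_ven R: outflow resistance into the atrium.
  # pulm_art C, pulm_art R, pulm_ven R and R_pulm_bed are re-derived from the
  # stage targets at load time; values here are placeholders.
  aorta:     {C: 0.30, R: 0.015}
  vena_cava: {C: 78.0, R: 0.04}
  pulm_art:  {C: 7.0,  R: 0.005}
  pulm_ven:  {C: 20.0, R: 0.02}
  R_pulm_bed: 0.06
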