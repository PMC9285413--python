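# Methods

`gravicor` couples a closed-loop lumped-parameter (0D) model of the adult
female circulation to a cardiac growth-and-remodeling loop driven by stress
homeostasis, and uses the pair to simulate the maternal adaptation to
pregnancy: a non-pregnant baseline (NPC) plus four gestational stages (T1,
T2, T3, Term).

## Circulation model

The network is a single closed loop: left ventricle → aorta → six parallel
systemic organ beds (liver, stomach/intestines, kidneys, uterus, upper body,
lower body) → venae cavae → right atrium → right ventricle → pulmonary
arteries → pulmonary veins → left atrium → left ventricle.  Units are mmHg,
ml and s throughout.

**Chambers.** Each chamber is a time-varying elastance,
`p(t) = E(t)·(V(t) − Vp0)`, with a double-Hill activation

    E(t) = k · [g1/(1+g1)] · [1/(1+g2)] + Emin,
    g1 = ((t−t_onset)/τ1)^m1,   g2 = ((t−t_onset)/τ2)^m2,

where `k` is computed once per parameter set so that `max E = Emax` (dense
grid maximisation, relative accuracy ≲1e−8).  `t − t_onset` is wrapped
modulo the period, so the atrial onset is written as a negative number
(−0.17 s) and lands late in the beat without branching.  Time constants are
absolute (seconds) and held fixed across stages; an experiment with
period-proportional timing destabilised the right-ventricular shear-stress
rule (the RV dilation demand saturated at `Vp0 = 0`) and was abandoned.

**Valves.** Each of the four valves carries a flow state and an opening
fraction ζ ∈ [0,1]:

    L(ζ)·dq/dt = Δp − R_char·q − B(ζ)·q|q|,
    B = ρ/(2·Aeff²),  L = ρ·l_eff/Aeff,  Aeff = A_closed + (A_open−A_closed)·ζ,
    dζ/dt = K_open·Δp·(1−ζ)  if Δp > 0,  else  K_close·Δp·ζ.

`R_char` is the characteristic resistance of the downstream great vessel
(aorta, pulmonary artery) folded into the valve branch.  The leak area
`A_closed = 1e−4 cm²` doubles as a numerical guard: together with the
`L ∝ 1/Aeff` scaling it bounds the closed-valve flow relaxation rate at
`q/(2·l_eff·Aeff)`, keeping the system integrable by an explicit scheme
(a hard floor of 1e−10 cm² also protects against division by zero when a
zero leak area is configured).  Rate coefficients (50 and 40 /(mmHg·s))
shape transients, not beat means; the defaults reproduce the small
regurgitant spike at semilunar-valve closure and the E/A double peak of
mitral inflow.

**Vessels and organs.** Great vessels are compliances (volume states) with
series resistances; each systemic organ bed is a five-element
Rart–Cart–Rvb–Cven–Rven compartment.  States are volumes for every storage
element, flows for the valve branches, and the four ζ.  Mass conservation
is therefore exact by construction (the volume-state derivatives sum to
zero identically); the realised drift over a run is at round-off level and
asserted < 0.1%.

**Integration.** The default integrator is a fixed-step RK4 kernel
(numba-compiled, dt = 0.1 ms, ~8500 steps/beat) with the elastance waveform
pre-evaluated on the half-step grid.  The explicit choice is deliberate:
the remodeling loop needs thousands of beats, and with the valve law above
the fastest time scale (valve motion, ~1 ms) is comfortably resolved.
Beat means used by the remodeling loop (CO, MAP, per-chamber mean radius,
thickness, Laplace stress, valve-flow magnitudes) are accumulated at every
step inside the kernel, so they are independent of the waveform sampling
stride (0.5 ms).  An adaptive stiff path (`backend="scipy"`, LSODA on the
same assembled right-hand side, rtol 1e−6/atol 1e−8) serves as an
independent cross-check: one beat agrees with the kernel to ~0.1% in CO and
MAP (tested).  Periodic steady state is declared when beat-mean CO and MAP
change < 0.1% between consecutive beats with at least 30 beats simulated.

## Stage parameterisation

All vascular parameters derive from stage targets (weight, height, heart
rate, target CO, perfusion pressure PerfP, per-organ flow fractions):

    Rtot_i = PerfP / (fraction_i · CO),  split 5% arterial / 92% bed / 3% venous,
    Cart_i = τ_sys / Rvb_i,  Cven_i = 30·Cart_i,          τ_sys = 0.81 s.

The pulmonary circulation uses the same split with its own constant
perfusion drop (5.5 mmHg, an assumption) and τ_pul = 0.5 s; its venous
compliance is an explicit configuration value (20 ml/mmHg) because a 30×
ratio there would store an unphysiological ~1.3 L.  Valve areas scale per
stage (+5/+8/+10/+10% from T1 to Term, an assumption where quantitative
data are scarce) with the tricuspid scale derived from
`tv = mv·pv/av`.  The 109 ml total myocardial volume is split among the
chambers with explicit stiffness/contractility-weighted fractions
(LV 0.776, RV 0.154, LA 0.045, RA 0.025), making the baseline LV mass
1.04 g/ml × 84.58 ml = 88.0 g.  The thin right-atrial share keeps the
atrial thin-wall condition (h/r < 0.1) satisfied at every stage; with a
heavier RA wall the strong right-atrial growth at Term pushes h/r past the
validity bound of the Laplace formula.

**Baseline calibration.** The stressed blood volume is the single knob: the
blood-volume rule (below) rescales all volume/flow states each beat until
CO is within 0.2% of 4.9 L/min.  The organ pressure drop — and hence
PerfP and SVR — then follows from the resistance derivation, and MAP lands
at PerfP plus the caval drop plus the right-atrial pressure.  Remaining
fixture constants (chamber elastances, valve areas, great-vessel R/C) were
calibrated once so that the converged baseline reproduces the reference
female panel (SV ≈ 69 ml, EF ≈ 66%, MAP ≈ 82 mmHg, SVR ≈ 1300 dyn·s/cm⁵,
~6:1 ventricular pressure ratio, stressed volume ≈ 1.2 L); they are free
configuration, never hard-coded.

## Geometry and stress

Atria are spheres, the LV a half ellipsoid and the RV a quarter ellipsoid,
each with long semi-axis 3r, giving lumen volume `V = k·r³` with k = 4π/3,
2π and π respectively (configurable).  The wall of volume `vwall` is a
uniform shell; its thickness has the closed form
`h = (r³ + vwall/k)^(1/3) − r`.

* Ventricular myofiber stress (mmHg), evaluated at end-systole (the
  first downward zero crossing of the outlet-valve flow after its peak):
  `σf = Pes·r / (2h·(1 + h/(2r)))`, algebraically identical to the
  meridional force balance `σ·π(Ro²−Ri²) = P·π·Ri²`.
* Atrial stress: thin-wall Laplace `σf = P·r/(2h)`, averaged over the
  beat; a warning fires if h/r ≥ 0.1 anywhere.
* Chamber wall shear stress: `σwss = 4μ·q_chamber/(π·r̄³)` with
  `q_chamber = (mean inlet flow + mean |outlet flow|)/2` and `r̄` the
  beat-mean radius; μ = 0.035 poise (assumption).  σwss is computed in
  dyn/cm² and carried in Pa inside the remodeling loop (see below).

## Remodeling loops

Three per-beat update rules with a common 2% tolerance; each iteration
simulates one heartbeat from the previous end state:

1. **Blood volume** (both variants): `errCO = (CO_t − CO)/CO_t`; every
   volume and flow state of the end-of-beat vector is scaled by
   `1 + factCO·errCO`, factCO = 0.01.
2. **Myofiber stress** (CRA only, per chamber):
   `errσf = (σf − σf_t)/σf_t`; `vwall += factσf·errσf·σf_t`
   (factσf = 0.005), and Emax, Emin scale with the wall-volume ratio
   (more muscle → proportionally more force and stiffness).
3. **Wall shear stress** (CRA only, per chamber):
   `errσwss = (σwss − σwss_t)/σwss_t`; `Vp0 += factσwss·errσwss·σwss_t`
   (factσwss = 1000), dilating an over-sheared chamber.

When the joint check fails, the blood-volume rule is always applied (it
keeps driving CO toward its target while the slower stress rules act),
and the stress rules act on every chamber whose own error exceeds the
tolerance.  Convergence requires all applicable errors below 2% for ten
consecutive beats on a periodic waveform.  Guards absent from the
conceptual algorithm: a wall-volume step is clamped at −50% per iteration
and Vp0 at zero, both with warnings; the iteration cap is 2000 beats with
a full error-history trace.

**Units of the σwss step.** The additive Vp0 update mixes a stress with a
volume, so the unit of σwss_t sets the step size.  Stability of the fixed-
point iteration requires `factσwss·σwss_t / V ≲ 2`; with physiologic
targets (~0.3 dyn/cm² ≈ 0.03 Pa) and chamber volumes of 50–100 ml, Pa
gives a contraction factor ~0.3–0.7 per beat while dyn/cm² overshoots and
oscillates.  σwss is therefore carried in Pa inside the loop and reported
in dyn/cm² elsewhere.

**Targets.** The homeostatic σf/σwss targets of every chamber are taken
from the converged calibrated baseline beat itself, which makes the
baseline a fixed point of the controlled loop by construction (tested: CRA
at NPC converges with zero net remodeling).  The rate factors set the
convergence speed, not the solution: halving all three reproduces the
converged geometry within a few percent (tested at T1).

An alternative schedule (`update_schedule="per_run"`) lets the circulation
settle several beats between updates; it reaches the same fixed point and
exists mainly for comparison.

**Boundary solutions.** The dilation rule cannot drive an unstressed
volume below zero.  If a chamber sits at `Vp0 = 0` with a persistently
negative shear-stress error (computed below target), no feasible update
remains and the loop accepts the boundary solution instead of iterating
forever.  This occurs only in the +20% leg of the stress-target scan,
where the right ventricle is the affected chamber: its wall thins
four-fold under the raised σf target, its elastances scale down with the
wall volume, and the softened chamber dilates passively — so its mean
radius ends *larger* than in the unscaled run even though its mass and
thickness are strictly smaller.  The inverse stress-size relationship
therefore holds for myocardial volume and thickness in all four chambers
and for the radius in all but that boundary-pinned case.

## Clinical panel conventions

* SBP/DBP/MAP from the aortic waveform; CO = beat-mean aortic valve flow;
  SV = its integral over the beat.
* EF = 100·SV/LVEDV with SV from aortic outflow and LVEDV the diastolic
  maximum; the forward-flow convention reconciles the reference panel's
  SV/LVEDV/EF triplet.
* SVR = 1333.22·(MAP − mean RA pressure)/CO[ml/s] in dyn·s/cm⁵ (venous
  pressure subtracted; the convention that reproduces the reference value
  from MAP ≈ 82 with a small positive right-atrial pressure).
* LVM = 1.04 g/ml · vwall_LV; LVEDD = 2·r_LV at mitral-valve closure
  (fallback: LV volume maximum); LAD = 2·(beat-mean LA radius);
  RWT = 2·h_LV(ED)/LVEDD.
* Stressed volume VTOTS = sum of beat-mean volumes of every compartment
  and chamber.  At baseline, total volume VTOT = VTOTS/0.3 (70/30
  unstressed/stressed split); in pregnancy VTOT(s) = VTOTS_stage +
  VTOTU_NPC·(1+s) for an unstressed-volume rise s ∈ [0, 0.33].

## Problem sizes and runtimes

The default study uses the full 28-state network (6 organ beds), dt =
0.1 ms (~8500 steps per beat).  Baseline calibration converges in ~500
beats (~15 s on one CPU); a controlled stage run takes 700–1500 beats
(30–60 s).  These sizes are the package defaults, not reduced variants:
the complete acceptance recomputation (baseline + Term CRA) runs in a few
minutes.

## Known limitations and discrepancies

* The LV growth predicted at the late stages overshoots the reference
  trajectory: the converged Term LV mass is ≈ +50% over baseline
  (reference: +40%), with mean-wall-thickness +19% (reference +14%),
  while T1 (+7% vs +4.5%) and T2 (+16% vs +17%) agree well, as do the
  diameter changes (LVEDD +10% vs +9%, LAD +11% vs +13%) and the volume
  bookkeeping (stressed volume 1.2 → 2.05 L).  The overshoot is
  structural, not numerical: holding the end-systolic force balance at
  fixed Pes makes the converged wall volume exactly proportional to the
  end-systolic lumen volume, and the shear-stress rule inflates
  end-systolic volume through the unstressed-volume term (the wall growth
  itself feeds back by stiffening diastole, shifting stored volume into
  Vp0).  The reference trajectory implies an end-systolic volume ratio
  smaller than its mass ratio, which the stated force balance cannot
  produce at constant end-systolic pressure; the discrepancy is documented
  rather than patched.
* Right-atrial myocardial growth is large (×3) because the right-atrial
  stress target is small and the mean right-atrial pressure roughly
  doubles under volume loading; the thin RA wall share keeps the Laplace
  assumption valid throughout.
* No chamber–chamber mechanical interaction, baroreflex, hormonal
  modulation, 1D wave propagation or fetal circulation; pregnancy enters
  only through the prescribed stage targets.
* The Poiseuille σwss expression is a deliberate first-order surrogate
  and does not strictly apply to the chamber geometries.
* Absolute atrial/ventricular diameters run high for the idealised
  shapes (as acknowledged for this class of geometry); percentage changes
  are the meaningful outputs.
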