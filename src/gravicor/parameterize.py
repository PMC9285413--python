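"""Stage-level parameter derivation and baseline calibration.

All vascular parameters are generated from a handful of stage targets: the
target cardiac output CO, the perfusion pressure PerfP driving the systemic
organ beds, the fraction of CO each organ receives, and prescribed RC time
constants for the systemic (tau_sys = 0.81 s) and pulmonary (tau_pul =
0.5 s) circulations.  For each organ::

    Rtot = PerfP / (fraction * CO)        (CO in ml/s)
    Rart = 0.05 Rtot,  Rvb = 0.92 Rtot,  Rven = 0.03 Rtot
    Cart = tau / Rvb,  Cven = 30 Cart

The pulmonary circulation uses the same split with its own (constant)
perfusion-pressure drop and tau_pul, with the venous compliance kept as an
explicit configuration value.

The non-pregnant (NPC) baseline is calibrated by adjusting the circulating
stressed blood volume until the simulated CO meets its target; the organ
pressure drop (and hence SVR) then follows from the resistance derivation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CalibrationError, ConfigError
from .hemo import CHAMBER_ORDER, NetworkConfig, OrganParams

__all__ = [
    "STAGES",
    "StageConfig",
    "CalibrationResult",
    "organ_compartment_params",
    "pulmonary_params",
    "schlich_bsa",
    "tricuspid_area_scale",
    "distribute_myocardium",
    "build_stage_network",
    "calibrate_npc",
]

STAGES = ("NPC", "T1", "T2", "T3", "Term")

LMIN_TO_MLS = 1000.0 / 60.0


@dataclass
class StageConfig:
    """Targets and inputs of one gestational stage."""

    stage: str
    weight_kg: float
    height_cm: float
    hr_bpm: float
    co_target_lmin: float
    perfusion_pressure_mmhg: float
    flow_fractions: dict  # organ name -> fraction of CO
    valve_area_scale: dict = field(default_factory=dict)  # MV/AV/PV vs NPC
    tau_sys: float = 0.81
    tau_pul: float = 0.5

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ConfigError(f"unknown stage {self.stage!r}")
        if self.co_target_lmin <= 0 or self.perfusion_pressure_mmhg <= 0:
            raise ConfigError(f"{self.stage}: CO and PerfP must be positive")
        total = sum(self.flow_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(
                f"{self.stage}: flow fractions sum to {total}, expected 1.0"
            )

    @property
    def co_target_mls(self):
        return self.co_target_lmin * LMIN_TO_MLS


@dataclass
class CalibrationResult:
    state: np.ndarray  # converged state vector of the calibrated baseline
    achieved: dict  # CO (L/min), MAP, PerfP, mRAP ...
    residuals: dict  # relative errors vs targets
    vp0_adjustments: dict  # per-element unstressed-volume changes applied
    volume_scale: float  # net multiplicative change of the initial volumes
    iterations: int


def organ_compartment_params(name, perfp_mmhg, co_lmin, fraction, tau_s):
    """Derive one organ's five-element parameters from stage targets."""
    if fraction <= 0 or fraction >= 1:
        raise ConfigError(f"{name}: flow fraction must lie in (0, 1)")
    if perfp_mmhg <= 0 or co_lmin <= 0 or tau_s <= 0:
        raise ConfigError(f"{name}: targets must be positive")
    rtot = perfp_mmhg / (fraction * co_lmin * LMIN_TO_MLS)
    rvb = 0.92 * rtot
    cart = tau_s / rvb
    return OrganParams(
        name=name,
        Rart=0.05 * rtot,
        Rvb=rvb,
        Rven=0.03 * rtot,
        Cart=cart,
        Cven=30.0 * cart,
    )


def pulmonary_params(perfp_pul_mmhg, co_lmin, tau_pul_s):
    """Pulmonary R/C from the pulmonary perfusion drop and tau_pul.

    Returns (R_char, R_bed, R_ven, C_art): characteristic resistance folded
    into the pulmonary-valve branch, microvascular bed resistance, venous
    outflow resistance, and arterial compliance.
    """
    rtot = perfp_pul_mmhg / (co_lmin * LMIN_TO_MLS)
    rvb = 0.92 * rtot
    return 0.05 * rtot, rvb, 0.03 * rtot, tau_pul_s / rvb


def schlich_bsa(weight_kg, height_cm):
    """Female-specific Schlich body surface area (m^2)."""
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be positive")
    return 0.000975482 * weight_kg**0.46 * height_cm**1.08


def tricuspid_area_scale(mv_scale, pv_scale, av_scale):
    """Tricuspid area scale from the proportionality rule tv = mv*pv/av."""
    if min(mv_scale, pv_scale, av_scale) <= 0:
        raise ConfigError("valve area scales must be positive")
    return mv_scale * pv_scale / av_scale


def distribute_myocardium(total_vmyo_ml, chambers, mode="Emax", fractions=None):
    """Split the total myocardial volume among the four chambers.

    mode: "Emax" (weights = each chamber's maximum elastance),
    "Emax+Emin", or "explicit" (``fractions`` maps chamber name to share).
    Returns a dict chamber name -> vwall (ml) summing to the total.
    """
    if total_vmyo_ml <= 0:
        raise ConfigError("total myocardial volume must be positive")
    names = [c.name for c in chambers]
    if mode == "explicit":
        if not fractions:
            raise ConfigError("explicit distribution requires fractions")
        w = np.array([float(fractions[n]) for n in names])
    elif mode == "Emax":
        w = np.array([c.Emax for c in chambers])
    elif mode == "Emax+Emin":
        w = np.array([c.Emax + c.Emin for c in chambers])
    else:
        raise ConfigError(f"unknown distribution mode {mode!r}")
    s = w.sum()
    if s <= 0:
        raise ConfigError("all distribution weights are zero")
    vw = total_vmyo_ml * w / s
    return dict(zip(names, vw))


def build_stage_network(stage: StageConfig, npc_base: NetworkConfig) -> NetworkConfig:
    """Per-stage network: organ and pulmonary parameters re-derived from the
    stage targets, heart rate set, valve areas scaled relative to NPC.

    Chamber parameters and the remaining great-vessel parameters (aortic
    and caval compliances and resistances, pulmonary venous compliance) are
    carried over unchanged; the remodeling loop owns the heart.
    """
    net = npc_base.copy()
    net.hr_bpm = stage.hr_bpm
    net.organs = {
        name: organ_compartment_params(
            name, stage.perfusion_pressure_mmhg, stage.co_target_lmin,
            fraction, stage.tau_sys,
        )
        for name, fraction in stage.flow_fractions.items()
    }
    perfp_pul = net.meta.get("pulm_perfusion_mmhg", 6.0)
    r_char, r_bed, r_ven, c_pa = pulmonary_params(
        perfp_pul, stage.co_target_lmin, stage.tau_pul
    )
    net.vessels.pulm_art.R = r_char
    net.vessels.pulm_art.C = c_pa
    net.vessels.R_pulm_bed = r_bed
    net.vessels.pulm_ven.R = r_ven

    scale = {v: float(stage.valve_area_scale.get(v, 1.0)) for v in ("MV", "AV", "PV")}
    scale["TV"] = tricuspid_area_scale(scale["MV"], scale["PV"], scale["AV"])
    for v, s in scale.items():
        net.valves[v].A_open = npc_base.valves[v].A_open * s
    return net


def calibrate_npc(
    net: NetworkConfig,
    targets,
    init=None,
    tolerance=0.005,
    max_iter=600,
    dt=1e-4,
    backend="auto",
):
    """Calibrate the NPC baseline by adjusting the circulating volume.

    ``targets`` maps at least ``CO`` (L/min); ``MAP`` and ``PerfP`` (mmHg)
    are reported if given.  The stressed blood volume is the single knob:
    the cardiac-output rule scales all volume/flow states each beat until
    the simulated CO meets the target (the organ pressure drop, and hence
    PerfP, then follows from the resistance derivation).  Equivalent to the
    unstressed-volume adjustment of the baseline set-up: shifting Vp0 and
    shifting the stored stressed volume move the same operating point.
    """
    from . import remodeling
    from .hemo import default_initial_state

    if targets.get("CO", 0) <= 0:
        raise CalibrationError("calibration requires a positive CO target")
    y0 = default_initial_state(net) if init is None else np.asarray(init, float).copy()
    v0 = float(np.sum(y0[: 8 + 2 * len(net.organs)]))
    rt = remodeling.RemodelingTargets(co_target_lmin=targets["CO"], tolerance=tolerance)
    try:
        res = remodeling.run_remodeling(
            net, y0, rt, mode="NCRA", dt=dt, max_iter=max_iter, backend=backend,
        )
    except Exception as exc:
        raise CalibrationError(f"NPC calibration did not converge: {exc}") from exc
    beat = res.beat
    from . import clinical

    m = clinical.beat_metrics(beat)
    achieved = {
        "CO": m["CO_lmin"],
        "MAP": m["MAP_mmHg"],
        "PerfP": m["PerfP_mmHg"],
        "mRAP": m["mRAP_mmHg"],
    }
    residuals = {"CO": (achieved["CO"] - targets["CO"]) / targets["CO"]}
    for key in ("MAP", "PerfP"):
        if key in targets:
            residuals[key] = (achieved[key] - targets[key]) / targets[key]
    v1 = beat.total_volume()
    return CalibrationResult(
        state=beat.y_end,
        achieved=achieved,
        residuals=residuals,
        vp0_adjustments={},
        volume_scale=v1 / v0,
        iterations=res.state.iteration,
    )
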