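"""Clinical variable panel, blood-volume bookkeeping and report tables.

Conventions (chosen to match standard echo/catheter definitions):

* SBP/DBP/MAP from the aortic pressure waveform; CO as the beat-mean aortic
  valve flow; SV as its integral over the beat.
* EF = 100 * SV / LVEDV with SV from aortic outflow (the forward-flow
  convention; it differs from the volumetric (EDV-ESV)/EDV by valve
  regurgitation).
* SVR = 1333.22 * (MAP - mean RA pressure) / CO[ml/s], in dyn·s/cm^5.
* Chamber mass M = rho_myo * Vmyo with rho_myo = 1.04 g/ml.
* RWT = 2*h_LV(end-diastole)/LVEDD; LVEDD = 2*r_LV at mitral-valve closure;
  LAD = 2 * beat-mean LA radius.
* Total stressed volume VTOTS = sum of the beat-mean volumes of every
  compartment and chamber.  At baseline the total blood volume is assumed
  to be 70% unstressed / 30% stressed; in pregnancy the unstressed part is
  scanned from +0% to +33% of its baseline value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AnalysisError, ConfigError
from .hemo import CHAMBER_ORDER, BeatRecord

__all__ = [
    "MYOCARDIAL_DENSITY",
    "MMHG_ML_TO_DYN",
    "ClinicalReport",
    "beat_metrics",
    "chamber_metrics",
    "volume_bookkeeping",
    "percentage_change_table",
    "clinical_report",
]

MYOCARDIAL_DENSITY = 1.04  # g/ml
MMHG_ML_TO_DYN = 1333.22  # mmHg·s/ml -> dyn·s/cm^5
STRESSED_FRACTION_NPC = 0.30


def _end_diastole_index(beat: BeatRecord):
    """Sample index/weight of mitral closure (first downward zero crossing
    of mitral flow); falls back to the LV volume maximum."""
    q = beat.valve_flow("MV")
    v = beat.chamber_volume("LV")
    n = len(q)
    cross = np.nonzero((q[:-1] > 0) & (q[1:] <= 0))[0]
    # closure belongs to early beat (ventricular activation at t=0) or to the
    # very end of diastole; accept a crossing in the first 20% of the beat
    early = cross[cross < 0.2 * n]
    if early.size:
        i = int(early[0])
        denom = q[i] - q[i + 1]
        w = float(q[i] / denom) if denom != 0 else 0.0
        return i, w
    return int(np.argmax(v)), 0.0


def beat_metrics(beat: BeatRecord):
    """Pressure/flow panel of one converged beat."""
    p_ao = beat.vessel_pressure("aorta")
    if p_ao.size == 0:
        raise AnalysisError("beat record carries no samples")
    t = beat.time
    span = t[-1] - t[0]
    co_mls = beat.mean_valve_flow("AV")
    co = co_mls * 60.0 / 1000.0
    sv = co_mls * beat.period
    v_lv = beat.chamber_volume("LV")
    v_rv = beat.chamber_volume("RV")
    lvedv = float(np.max(v_lv))
    map_ = beat.mean_aortic_pressure()
    mrap = beat.mean_chamber_pressure("RA")
    p_vc = beat.vessel_pressure("vena_cava")
    mvc = float(np.trapezoid(p_vc, t) / span)
    metrics = {
        "HR_bpm": beat.hr_bpm,
        "SBP_mmHg": float(np.max(p_ao)),
        "DBP_mmHg": float(np.min(p_ao)),
        "MAP_mmHg": map_,
        "CO_lmin": co,
        "SV_ml": sv,
        "LVEDV_ml": lvedv,
        "LVESV_ml": float(np.min(v_lv)),
        "RVEDV_ml": float(np.max(v_rv)),
        "RVESV_ml": float(np.min(v_rv)),
        "EF_pct": 100.0 * sv / lvedv,
        "CW_mmHg_lmin": co * map_,
        "mRAP_mmHg": mrap,
        "PerfP_mmHg": map_ - mvc,
        "SVR_dyn_s_cm5": MMHG_ML_TO_DYN * (map_ - mrap) / co_mls,
    }
    return metrics


def chamber_metrics(beat: BeatRecord, density=MYOCARDIAL_DENSITY):
    """Mass and geometry indices of the heart chambers."""
    i, w = _end_diastole_index(beat)

    def at_ed(series):
        s = np.asarray(series, dtype=float)
        j = min(i + 1, len(s) - 1)
        return float((1.0 - w) * s[i] + w * s[j])

    r_ed = at_ed(beat.chamber_radius("LV"))
    h_ed = at_ed(beat.chamber_thickness("LV"))
    lvedd = 2.0 * r_ed
    lad = 2.0 * (beat.mean_radius("LA") or float(np.mean(beat.chamber_radius("LA"))))
    out = {
        "LVM_g": density * beat.chamber_vwall("LV"),
        "LVEDD_cm": lvedd,
        "hLVED_cm": h_ed,
        "RWT": 2.0 * h_ed / lvedd,
        "LAD_cm": lad,
    }
    for c in CHAMBER_ORDER:
        out[f"Vmyo_{c}_ml"] = beat.chamber_vwall(c)
        out[f"mass_{c}_g"] = density * beat.chamber_vwall(c)
        rm = beat.mean_radius(c)
        hm = beat.mean_thickness(c)
        out[f"r_mean_{c}_cm"] = rm if rm is not None else float(np.mean(beat.chamber_radius(c)))
        out[f"h_mean_{c}_cm"] = hm if hm is not None else float(np.mean(beat.chamber_thickness(c)))
    return out


def volume_bookkeeping(beat: BeatRecord, npc_vtots_l=None, scenario=0.0):
    """Stressed/unstressed/total blood-volume accounting, litres.

    For the baseline itself pass ``npc_vtots_l=None``: the total volume is
    then reconstructed from the 70/30 unstressed/stressed split.  For a
    pregnancy stage pass the baseline stressed volume; the total becomes
    VTOTS_stage + VTOTU_NPC*(1+s) with the unstressed-volume rise s in
    [0, 0.33].
    """
    if not (0.0 <= scenario <= 0.33):
        raise ConfigError("unstressed-volume rise scenario must lie in [0, 0.33]")
    vtots = beat.mean_total_volume() / 1000.0
    if npc_vtots_l is None:
        npc_vtots_l = vtots
    vtot_npc = npc_vtots_l / STRESSED_FRACTION_NPC
    vtotu_npc = vtot_npc - npc_vtots_l
    out = {
        "VTOTS_l": vtots,
        "VTOTU_NPC_l": vtotu_npc,
        "VTOT_NPC_l": vtot_npc,
    }
    for s, key in ((0.0, "0"), (0.33, "33"), (scenario, "s")):
        vtot = vtots + vtotu_npc * (1.0 + s)
        out[f"VTOT_{key}_l"] = vtot
        out[f"dVTOT_{key}_pct"] = 100.0 * (vtot - vtot_npc) / vtot_npc
    return out


def percentage_change_table(npc_report, stage_reports):
    """Per-metric percentage change of each stage from the baseline.

    ``stage_reports`` maps stage name to a metrics dict sharing keys with
    ``npc_report``.  Metrics whose baseline value is zero are reported as
    missing (NaN).
    """
    import pandas as pd

    rows = {}
    for stage, rep in stage_reports.items():
        row = {}
        for key, ref in npc_report.items():
            if key not in rep or not np.isscalar(ref):
                continue
            row[key] = 100.0 * (rep[key] - ref) / ref if ref != 0 else np.nan
        rows[stage] = row
    return pd.DataFrame(rows).T


_ROUNDING = {
    "SVR_dyn_s_cm5": 0, "SBP_mmHg": 1, "DBP_mmHg": 1, "MAP_mmHg": 1,
    "CO_lmin": 1, "SV_ml": 0, "EF_pct": 0, "CW_mmHg_lmin": 0,
    "LVEDV_ml": 0, "LVESV_ml": 0, "RVEDV_ml": 0, "RVESV_ml": 0,
    "LVM_g": 0, "RWT": 2, "LAD_cm": 1, "LVEDD_cm": 1,
}


@dataclass
class ClinicalReport:
    """Full-precision clinical panel of one converged run."""

    stage: str
    mode: str
    metrics: dict = field(default_factory=dict)

    def rounded(self):
        """Panel at the customary reporting precision."""
        out = {}
        for k, v in self.metrics.items():
            if k in _ROUNDING:
                out[k] = round(v, _ROUNDING[k]) if _ROUNDING[k] else round(v)
            else:
                out[k] = v
        return out

    def to_json(self, path):
        import json

        with open(path, "w") as fh:
            json.dump({"stage": self.stage, "mode": self.mode,
                       "metrics": self.metrics}, fh, indent=2, default=float)


def clinical_report(beat: BeatRecord, stage="NPC", mode="CRA",
                    npc_vtots_l=None, scenario=0.0) -> ClinicalReport:
    metrics = {}
    metrics.update(beat_metrics(beat))
    metrics.update(chamber_metrics(beat))
    metrics.update(volume_bookkeeping(beat, npc_vtots_l, scenario))
    return ClinicalReport(stage=stage, mode=mode, metrics=metrics)
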