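"""End-to-end pregnancy study orchestration.

Ties the pieces together: build the non-pregnant network from the fixtures,
calibrate it, freeze the homeostatic stress targets from the converged
baseline beat, and run the controlled (CRA) or uncontrolled (NCRA)
remodeling loop at any gestational stage.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import clinical, config, parameterize, remodeling
from .errors import ConfigError

__all__ = ["Baseline", "StageResult", "calibrate_baseline", "run_stage",
           "reproduce_tables", "scan_targets"]


@dataclass
class Baseline:
    net: object  # calibrated NPC NetworkConfig
    state: object  # converged state vector
    beat: object  # converged NPC BeatRecord
    calibration: object  # CalibrationResult
    stages: dict  # stage name -> StageConfig
    report: object  # ClinicalReport of the baseline

    @property
    def vtots_l(self):
        return self.report.metrics["VTOTS_l"]

    def targets_for(self, stage_name, tolerance=0.02):
        stage = self.stages[stage_name]
        return remodeling.stress_targets_from_beat(
            self.beat, stage.co_target_lmin, tolerance
        )


@dataclass
class StageResult:
    stage: str
    mode: str
    result: object  # RemodelingResult
    report: object  # ClinicalReport

    @property
    def beat(self):
        return self.result.beat

    @property
    def net(self):
        return self.result.net


def calibrate_baseline(base=None, stages=None, dt=1e-4, tolerance=0.002,
                       backend="auto") -> Baseline:
    """Build and calibrate the non-pregnant baseline."""
    stages = stages if isinstance(stages, dict) else config.load_stages(stages)
    net = config.build_npc_network(base, stages)
    npc = stages["NPC"]
    cal = parameterize.calibrate_npc(
        net,
        {"CO": npc.co_target_lmin, "PerfP": npc.perfusion_pressure_mmhg},
        tolerance=tolerance, dt=dt, backend=backend,
    )
    from .hemo import simulate_beat

    beat = simulate_beat(net, cal.state, dt=dt, backend=backend)
    report = clinical.clinical_report(beat, stage="NPC", mode="baseline")
    return Baseline(net=net, state=beat.y_end, beat=beat, calibration=cal,
                    stages=stages, report=report)


def run_stage(stage_name, mode, baseline: Baseline, target_scale=1.0,
              tolerance=0.02, dt=1e-4, max_iter=2000, backend="auto",
              update_schedule="per_beat") -> StageResult:
    """Run one gestational stage with the chosen remodeling variant."""
    if stage_name not in baseline.stages:
        raise ConfigError(f"unknown stage {stage_name!r}")
    if mode not in ("CRA", "NCRA"):
        raise ConfigError("mode must be 'CRA' or 'NCRA'")
    stage = baseline.stages[stage_name]
    net = parameterize.build_stage_network(stage, baseline.net)
    targets = baseline.targets_for(stage_name, tolerance)
    if target_scale != 1.0:
        targets = targets.scaled(target_scale)
    res = remodeling.run_remodeling(
        net, baseline.state, targets, mode=mode, dt=dt, max_iter=max_iter,
        backend=backend, update_schedule=update_schedule,
    )
    report = clinical.clinical_report(
        res.beat, stage=stage_name, mode=mode, npc_vtots_l=baseline.vtots_l
    )
    return StageResult(stage=stage_name, mode=mode, result=res, report=report)


def reproduce_tables(baseline: Baseline = None, stages=("T1", "T2", "T3", "Term"),
                     modes=("NCRA", "CRA"), **kwargs):
    """All stage/mode combinations plus the baseline, as one DataFrame.

    Returns (table, pct_change) where ``table`` has one column per run and
    ``pct_change`` the percentage changes of each run from the baseline.
    """
    import pandas as pd

    baseline = baseline or calibrate_baseline()
    reports = {"NPC": baseline.report.metrics}
    for mode in modes:
        for st in stages:
            r = run_stage(st, mode, baseline, **kwargs)
            reports[f"{st}/{mode}"] = r.report.metrics
    table = pd.DataFrame(reports)
    pct = clinical.percentage_change_table(
        baseline.report.metrics,
        {k: v for k, v in reports.items() if k != "NPC"},
    )
    return table, pct


def scan_targets(stage_name, baseline: Baseline = None, scales=(0.8, 1.0, 1.2),
                 **kwargs):
    """Stress-target sensitivity scan at one stage (CRA only)."""
    baseline = baseline or calibrate_baseline()
    stage = baseline.stages[stage_name]
    net = parameterize.build_stage_network(stage, baseline.net)
    targets = baseline.targets_for(stage_name)
    return remodeling.stress_target_scan(
        net, baseline.state, targets, scales=scales, **kwargs
    )
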