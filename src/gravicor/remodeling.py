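"""Growth-and-remodeling loops driven by stress homeostasis.

Two variants are coupled to the circulation model:

* **NCRA** (no controlled remodeling): only the blood-volume rule is
  active — the initial values of all volume and flow states are rescaled
  each beat until the simulated cardiac output meets the stage target.
  Heart structure (wall volumes, elastances, unstressed volumes) never
  changes.
* **CRA** (controlled remodeling): in addition to the blood-volume rule,
  each chamber's myofiber stress and endocardial wall shear stress are
  held at their homeostatic (non-pregnant) targets.  An excessive myofiber
  stress grows the wall (and scales both elastances with the wall volume,
  i.e. more muscle means proportionally more force and stiffness); an
  excessive wall shear stress dilates the chamber by raising its
  unstressed volume.

The three update rules, applied once per simulated heartbeat whenever the
corresponding error exceeds the 2% tolerance::

    errCO   = (CO_target - CO) / CO_target
    Y(0)   <- Y(T) * (1 + fact_co * errCO)            fact_co   = 0.01

    err_sf  = (sigma_f - sigma_f_target) / sigma_f_target
    vwall  <- vwall + fact_sf * err_sf * sigma_f_target       fact_sf = 0.005
    Emax   <- Emax * vwall_new / vwall_old   (idem Emin)

    err_wss = (sigma_wss - sigma_wss_target) / sigma_wss_target
    Vp0    <- Vp0 + fact_wss * err_wss * sigma_wss_target     fact_wss = 1000

Note the sign conventions: the CO error is (target - computed)/target while
both stress errors are (computed - target)/target, so a deficit in output
grows the circulating volume and an excess of stress grows/dilates the
chamber.  sigma_f is in mmHg; sigma_wss is carried in Pa for the additive
Vp0 step (see docs/methods.md for the gain analysis behind that choice).

The factors set the convergence rate, not the fixed point: the converged
geometry is independent of them (tested).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .errors import AnalysisError, ConvergenceError
from .hemo import CHAMBER_ORDER, NetworkConfig, StateLayout, simulate_beat

__all__ = [
    "FACT_CO",
    "FACT_SIGMA_F",
    "FACT_SIGMA_WSS",
    "RemodelingTargets",
    "RemodelingState",
    "RemodelingResult",
    "relative_error",
    "apply_co_rule",
    "apply_sigma_f_rule",
    "apply_wss_rule",
    "stress_targets_from_beat",
    "run_remodeling",
    "stress_target_scan",
]

log = logging.getLogger(__name__)

FACT_CO = 0.01
FACT_SIGMA_F = 0.005
FACT_SIGMA_WSS = 1000.0

VENTRICLES = ("LV", "RV")
ATRIA = ("LA", "RA")


@dataclass
class RemodelingTargets:
    """Homeostatic targets of one stage.

    ``sigma_f`` (mmHg) and ``sigma_wss`` (Pa) map chamber name to target;
    they may be None for NCRA runs.  The tolerance applies to all rules.
    """

    co_target_lmin: float
    sigma_f: dict | None = None
    sigma_wss: dict | None = None
    tolerance: float = 0.02

    def __post_init__(self):
        if self.co_target_lmin <= 0:
            raise ValueError("CO target must be positive")
        if not (0.0 < self.tolerance < 0.1):
            raise ValueError("tolerance must lie in (0, 0.1)")
        for d in (self.sigma_f, self.sigma_wss):
            if d is not None and any(v <= 0 for v in d.values()):
                raise ValueError("stress targets must be positive")

    def scaled(self, factor):
        """Both stress maps scaled by the same factor (target-scan support)."""
        sf = {k: v * factor for k, v in self.sigma_f.items()} if self.sigma_f else None
        sw = {k: v * factor for k, v in self.sigma_wss.items()} if self.sigma_wss else None
        return RemodelingTargets(self.co_target_lmin, sf, sw, self.tolerance)


@dataclass
class RemodelingState:
    """Per-iteration bookkeeping of the loop."""

    mode: str
    iteration: int = 0
    vwall: dict = field(default_factory=dict)
    Emax: dict = field(default_factory=dict)
    Emin: dict = field(default_factory=dict)
    Vp0: dict = field(default_factory=dict)
    err_co: float = np.inf
    err_sigma_f: dict = field(default_factory=dict)
    err_sigma_wss: dict = field(default_factory=dict)
    fact_co: float = FACT_CO
    fact_sigma_f: float = FACT_SIGMA_F
    fact_sigma_wss: float = FACT_SIGMA_WSS
    converged: bool = False

    def snapshot(self, net: NetworkConfig):
        for c in CHAMBER_ORDER:
            ch = net.chambers[c]
            self.vwall[c] = ch.vwall
            self.Emax[c] = ch.Emax
            self.Emin[c] = ch.Emin
            self.Vp0[c] = ch.Vp0

    def max_abs_error(self):
        errs = [abs(self.err_co)]
        errs += [abs(v) for v in self.err_sigma_f.values()]
        errs += [abs(v) for v in self.err_sigma_wss.values()]
        return max(errs)


@dataclass
class RemodelingResult:
    net: NetworkConfig
    state: RemodelingState
    beat: object  # BeatRecord of the converged periodic steady state
    trace: object  # DataFrame, one row per iteration


def relative_error(computed, target, kind):
    """Signed relative error with the rule-specific sign convention.

    kind="co": (target - computed)/target — a deficit is positive.
    kind="sigma_f" / "sigma_wss": (computed - target)/target — an excess is
    positive.
    """
    if target == 0:
        raise ZeroDivisionError("relative error undefined for zero target")
    if kind == "co":
        return (target - computed) / target
    if kind in ("sigma_f", "sigma_wss"):
        return (computed - target) / target
    raise ValueError(f"unknown rule kind {kind!r}")


def apply_co_rule(y, layout: StateLayout, err_co, fact_co=FACT_CO):
    """Rescale the end-of-beat state to nudge the next beat's output.

    Every volume and flow state is multiplied by (1 + pCO/100) with
    pCO = fact_co * errCO * 100; valve opening fractions are left alone.
    """
    pco = fact_co * err_co * 100.0
    out = np.asarray(y, dtype=float).copy()
    n_vf = layout.valve_zeta.start  # volumes + flows precede the zetas
    out[:n_vf] *= 1.0 + pco / 100.0
    return out


def apply_sigma_f_rule(chamber, err, sigma_f_target, fact=FACT_SIGMA_F):
    """Grow/shrink the wall and rescale elastances; mutates ``chamber``."""
    v_old = chamber.vwall
    v_new = fact * err * sigma_f_target + v_old
    if v_new <= 0.5 * v_old:
        warnings.warn(
            f"{chamber.name}: wall-volume step clamped (pathological shrink)",
            RuntimeWarning,
            stacklevel=2,
        )
        v_new = 0.5 * v_old
    ratio = v_new / v_old
    chamber.vwall = v_new
    chamber.Emax *= ratio
    chamber.Emin *= ratio
    return chamber


def apply_wss_rule(chamber, err, sigma_wss_target_pa, fact=FACT_SIGMA_WSS):
    """Dilate/shrink the chamber through its unstressed volume; mutates it."""
    vp0 = fact * err * sigma_wss_target_pa + chamber.Vp0
    if vp0 < 0.0:
        warnings.warn(
            f"{chamber.name}: unstressed volume clamped at zero",
            RuntimeWarning,
            stacklevel=2,
        )
        vp0 = 0.0
    chamber.Vp0 = vp0
    return chamber


def _beat_stresses(beat, mu_poise, shape_coefficients):
    """(sigma_f mmHg, sigma_wss Pa) per chamber from one beat."""
    sf = {}
    wss = {}
    for c in VENTRICLES:
        sf[c] = geometry.ventricular_end_systolic_stress(beat, c, shape_coefficients)
    for c in ATRIA:
        sf[c] = geometry.atrial_mean_stress(beat, c, shape_coefficients)
    for c in CHAMBER_ORDER:
        wss[c] = geometry.DYN_PER_CM2_TO_PA * geometry.chamber_wall_shear_stress(
            beat, c, mu_poise, shape_coefficients
        )
    return sf, wss


def stress_targets_from_beat(beat, co_target_lmin, tolerance=0.02):
    """Homeostatic targets taken from a converged (baseline) beat.

    The non-pregnant values of sigma_f and sigma_wss become the per-chamber
    targets enforced at every later stage, which also makes the baseline a
    fixed point of the controlled loop by construction.
    """
    net = beat.net
    sf, wss = _beat_stresses(beat, net.blood.mu_poise, net.shape_coefficients)
    return RemodelingTargets(
        co_target_lmin=co_target_lmin,
        sigma_f=sf,
        sigma_wss=wss,
        tolerance=tolerance,
    )


def run_remodeling(
    net: NetworkConfig,
    y0,
    targets: RemodelingTargets,
    mode="CRA",
    dt=1e-4,
    max_iter=2000,
    settle_beats=10,
    periodic_tol=1e-3,
    update_schedule="per_beat",
    fact_co=FACT_CO,
    fact_sigma_f=FACT_SIGMA_F,
    fact_sigma_wss=FACT_SIGMA_WSS,
    backend="auto",
) -> RemodelingResult:
    """Run the remodeling loop at one stage until homeostasis.

    Each iteration simulates one heartbeat from the previous end state,
    evaluates the applicable errors, and applies the update rules to any
    that exceed the tolerance (``update_schedule="per_run"`` instead lets
    the circulation settle for several beats between updates).  The loop is
    converged when every applicable |error| < tolerance over
    ``settle_beats`` consecutive beats with no updates applied and the beat
    is periodic (CO and MAP changing < 0.1% beat to beat).

    NCRA evaluates and acts on the CO error only and leaves vwall, Emax,
    Emin and Vp0 untouched.
    """
    if mode not in ("CRA", "NCRA"):
        raise ValueError("mode must be 'CRA' or 'NCRA'")
    if mode == "CRA" and (targets.sigma_f is None or targets.sigma_wss is None):
        raise ValueError("CRA requires sigma_f and sigma_wss targets for all chambers")
    if update_schedule not in ("per_beat", "per_run"):
        raise ValueError(f"unknown update schedule {update_schedule!r}")
    settle_every = 1 if update_schedule == "per_beat" else 5

    net = net.copy()
    layout = StateLayout(len(net.organs))
    y = np.asarray(y0, dtype=float).copy()
    tol = targets.tolerance
    state = RemodelingState(
        mode=mode, fact_co=fact_co, fact_sigma_f=fact_sigma_f,
        fact_sigma_wss=fact_sigma_wss,
    )
    state.snapshot(net)

    trace_rows = []
    streak = 0
    prev_co = prev_map = None
    beat = None
    beats_since_update = settle_every  # allow updating on the first beat
    for it in range(1, max_iter + 1):
        beat = simulate_beat(net, y, dt=dt, backend=backend)
        y = beat.y_end
        co = beat.cardiac_output()
        map_ = beat.mean_aortic_pressure()
        periodic = (
            prev_co is not None
            and abs(co - prev_co) / max(co, 1e-9) < periodic_tol
            and abs(map_ - prev_map) / max(map_, 1e-9) < periodic_tol
        )
        prev_co, prev_map = co, map_

        state.iteration = it
        state.err_co = relative_error(co, targets.co_target_lmin, "co")
        if mode == "CRA":
            try:
                sf, wss = _beat_stresses(beat, net.blood.mu_poise, net.shape_coefficients)
            except AnalysisError:
                sf = wss = None  # transient beat without ejection: CO rule only
            if sf is not None:
                state.err_sigma_f = {
                    c: relative_error(sf[c], targets.sigma_f[c], "sigma_f")
                    for c in CHAMBER_ORDER
                }
                state.err_sigma_wss = {
                    c: relative_error(wss[c], targets.sigma_wss[c], "sigma_wss")
                    for c in CHAMBER_ORDER
                }

        row = {"iteration": it, "CO_lmin": co, "MAP_mmHg": map_, "err_co": state.err_co}
        for c in CHAMBER_ORDER:
            row[f"err_sf_{c}"] = state.err_sigma_f.get(c, np.nan)
            row[f"err_wss_{c}"] = state.err_sigma_wss.get(c, np.nan)
            row[f"vwall_{c}"] = net.chambers[c].vwall
            row[f"Vp0_{c}"] = net.chambers[c].Vp0
        trace_rows.append(row)

        within = abs(state.err_co) < tol
        if mode == "CRA":
            within = within and all(abs(v) < tol for v in state.err_sigma_f.values())
            # a chamber pinned at zero unstressed volume with a negative
            # shear error has no feasible update left: accept the boundary
            # solution instead of iterating forever (documented guard)
            within = within and all(
                abs(v) < tol or (v < 0 and net.chambers[c].Vp0 <= 0.0)
                for c, v in state.err_sigma_wss.items()
            )

        if within:
            streak += 1
            beats_since_update += 1
            if streak >= settle_beats and periodic:
                state.converged = True
                state.snapshot(net)
                break
            continue

        streak = 0
        beats_since_update += 1
        if beats_since_update < settle_every:
            continue  # per_run schedule: let the circulation settle first
        beats_since_update = 0
        # the joint convergence check failed, so the blood-volume rule is
        # always applied (it keeps driving CO toward target while the slower
        # stress rules converge); stress rules act per offending chamber
        y = apply_co_rule(y, layout, state.err_co, fact_co)
        if mode == "CRA" and state.err_sigma_f:
            for c in CHAMBER_ORDER:
                if abs(state.err_sigma_f[c]) >= tol:
                    apply_sigma_f_rule(
                        net.chambers[c], state.err_sigma_f[c],
                        targets.sigma_f[c], fact_sigma_f,
                    )
                if abs(state.err_sigma_wss[c]) >= tol:
                    apply_wss_rule(
                        net.chambers[c], state.err_sigma_wss[c],
                        targets.sigma_wss[c], fact_sigma_wss,
                    )
        if it % 100 == 0:
            log.info(
                "remodeling %s it=%d CO=%.3f max|err|=%.4f",
                mode, it, co, state.max_abs_error(),
            )

    import pandas as pd

    trace = pd.DataFrame(trace_rows)
    if not state.converged:
        raise ConvergenceError(
            f"{mode} did not converge within {max_iter} beats "
            f"(max |err| = {state.max_abs_error():.4f})",
            residuals={"err_co": state.err_co,
                       "err_sigma_f": dict(state.err_sigma_f),
                       "err_sigma_wss": dict(state.err_sigma_wss)},
            history=trace,
        )
    state.snapshot(net)
    beat.n_beat = state.iteration
    return RemodelingResult(net=net, state=state, beat=beat, trace=trace)


def stress_target_scan(net, y0, targets, scales=(0.8, 1.0, 1.2), mode="CRA", **kwargs):
    """Re-run the controlled loop with both stress targets scaled together.

    Returns a DataFrame with one row per (scale, chamber) carrying the
    converged myocardial volume, beat-mean radius and thickness.  The
    expected inverse stress-size relationship: larger targets, smaller
    chambers.
    """
    import pandas as pd

    if mode != "CRA":
        raise ValueError("the stress-target scan is defined for CRA only")
    rows = []
    for s in scales:
        res = run_remodeling(net, y0, targets.scaled(s), mode=mode, **kwargs)
        for c in CHAMBER_ORDER:
            rows.append({
                "scale": s,
                "chamber": c,
                "Vmyo_ml": res.net.chambers[c].vwall,
                "r_cm": res.beat.mean_radius(c),
                "h_cm": res.beat.mean_thickness(c),
            })
    return pd.DataFrame(rows)
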