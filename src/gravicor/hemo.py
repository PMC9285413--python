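"""Closed-loop 0D circulation: elastance chambers, dynamic valves, organ and
great-vessel compartments, ODE assembly and integration to periodic steady
state.

Model layout (one closed loop)::

    LV --AV--> aorta --> {liver, gut, kidneys, uterus, upper, lower body}
       --> vena cava --> RA --TV--> RV --PV--> pulmonary arteries
       --> pulmonary veins --> LA --MV--> LV

Each heart chamber is a time-varying elastance ``p = E(t) * (V - Vp0)`` with
a double-Hill activation waveform.  Each of the four valves follows a
Bernoulli pressure-flow law with a blood inertance and a pressure-driven
opening-fraction state.  Every systemic organ is a five-element
Rart-Cart-Rvb-Cven-Rven compartment; the four great vessels (aorta, venae
cavae, pulmonary arteries, pulmonary veins) are compliances with series
resistances.

Units are mmHg, ml, s throughout; valve areas in cm^2, blood density in
g/ml (the 1333.22 dyn·s/cm^5 per mmHg·s/ml conversion is applied inside the
valve law).

State convention: volumes are states for every storage element (pressures
derived), flows are states for the four valve branches, and the opening
fractions ``zeta`` are states for the valves.  Mass conservation is then
exact by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, ConvergenceError, IntegrationError, ParameterError
from .geometry import SHAPE_COEFFICIENTS, lumen_radius, wall_thickness

__all__ = [
    "CHAMBER_ORDER",
    "VALVE_ORDER",
    "ChamberParams",
    "ValveParams",
    "OrganParams",
    "GreatVesselParams",
    "GreatVessels",
    "BloodProperties",
    "NetworkConfig",
    "StateLayout",
    "BeatRecord",
    "elastance_at",
    "elastance_scale",
    "chamber_pressure",
    "valve_step",
    "assemble_odes",
    "default_initial_state",
    "simulate_beat",
    "run_to_periodic_steady_state",
]

MMHG = 1333.22  # dyn/cm^2 per mmHg

CHAMBER_ORDER = ("LV", "RV", "LA", "RA")
VALVE_ORDER = ("AV", "PV", "MV", "TV")
#: valve i connects chamber _VALVE_UP[i] to its downstream node
_VALVE_UP = (0, 1, 2, 3)  # LV, RV, LA, RA
#: downstream node of each valve: aorta, pulm art, LV, RV
_VALVE_DOWN_VESSEL = (0, 2, -1, -1)  # index into vessel volumes, -1 = chamber
_VALVE_DOWN_CHAMBER = (-1, -1, 0, 1)

_AEFF_FLOOR = 1e-10  # cm^2, numerical guard against division by zero


# --------------------------------------------------------------------------
# parameter containers


@dataclass
class ChamberParams:
    """Elastance, timing, unstressed-volume and wall description of one
    heart chamber."""

    name: str
    Emax: float  # mmHg/ml
    Emin: float  # mmHg/ml
    tau1: float  # s, contraction time constant
    tau2: float  # s, relaxation time constant
    m1: float
    m2: float
    t_onset: float = 0.0  # s; negative values wrap to late in the beat
    Vp0: float = 0.0  # ml, unstressed volume
    vwall: float = 10.0  # ml, myocardial wall volume
    shape: str = "sphere"

    def __post_init__(self):
        vals = (self.Emax, self.Emin, self.tau1, self.tau2, self.m1, self.m2,
                self.t_onset, self.Vp0, self.vwall)
        if not all(math.isfinite(v) for v in vals):
            raise ParameterError(f"{self.name}: non-finite chamber parameter")
        if not (self.Emax > self.Emin > 0):
            raise ParameterError(f"{self.name}: require Emax > Emin > 0")
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ParameterError(f"{self.name}: time constants must be positive")
        if self.Vp0 < 0:
            raise ParameterError(f"{self.name}: Vp0 must be non-negative")
        if self.vwall <= 0:
            raise ParameterError(f"{self.name}: vwall must be positive")
        if self.shape not in SHAPE_COEFFICIENTS:
            raise ConfigError(f"{self.name}: unknown shape {self.shape!r}")


@dataclass
class ValveParams:
    """Bernoulli valve with opening/closing dynamics.

    ``A_closed`` doubles as the numerical leak area; the default keeps the
    closed-valve flow negligible (< 0.2 ml/s at 40 mmHg) while bounding the
    relaxation rate of the flow state so the system stays non-stiff.
    """

    name: str
    A_open: float  # cm^2, effective area fully open
    A_closed: float = 1e-4  # cm^2, leak area
    K_open: float = 50.0  # 1/(mmHg s)
    K_close: float = 40.0  # 1/(mmHg s)
    blood_density: float = 1.06  # g/ml
    l_eff: float = 1.5  # cm, effective inertial length

    def __post_init__(self):
        if not (self.A_open > self.A_closed >= 0):
            raise ParameterError(f"{self.name}: require A_open > A_closed >= 0")
        if self.K_open <= 0 or self.K_close <= 0:
            raise ParameterError(f"{self.name}: rate coefficients must be positive")

    @property
    def B_coeff(self):
        """B = B_coeff / Aeff^2 gives mmHg s^2/ml^2."""
        return self.blood_density / (2.0 * MMHG)

    @property
    def L_coeff(self):
        """L = L_coeff / Aeff gives mmHg s^2/ml."""
        return self.blood_density * self.l_eff / MMHG


@dataclass
class OrganParams:
    """Five-element systemic organ bed: Rart-Cart-Rvb-Cven-Rven."""

    name: str
    Rart: float
    Rvb: float
    Rven: float
    Cart: float
    Cven: float

    def __post_init__(self):
        for attr in ("Rart", "Rvb", "Rven", "Cart", "Cven"):
            if getattr(self, attr) <= 0:
                raise ParameterError(f"{self.name}: {attr} must be positive")


@dataclass
class GreatVesselParams:
    """Compliance chamber with a series resistance (and optional inertance).

    For the aorta and pulmonary arteries ``R`` is the characteristic
    resistance folded into the upstream valve branch; for the venae cavae
    and pulmonary veins it is the outflow resistance into the atrium.
    """

    name: str
    R: float
    C: float
    L: float = 0.0

    def __post_init__(self):
        if self.R <= 0 or self.C <= 0:
            raise ParameterError(f"{self.name}: R and C must be positive")
        if self.L < 0:
            raise ParameterError(f"{self.name}: L must be non-negative")


@dataclass
class GreatVessels:
    aorta: GreatVesselParams
    vena_cava: GreatVesselParams
    pulm_art: GreatVesselParams
    pulm_ven: GreatVesselParams
    R_pulm_bed: float = 0.06  # mmHg s/ml, pulmonary microvascular resistance

    def as_tuple(self):
        return (self.aorta, self.vena_cava, self.pulm_art, self.pulm_ven)


@dataclass
class BloodProperties:
    mu_poise: float = 0.035  # dyn s/cm^2
    rho: float = 1.06  # g/ml


@dataclass
class NetworkConfig:
    """Complete description of the closed loop."""

    hr_bpm: float
    chambers: dict  # name -> ChamberParams, keys = CHAMBER_ORDER
    valves: dict  # name -> ValveParams, keys = VALVE_ORDER
    organs: dict  # name -> OrganParams (ordered)
    vessels: GreatVessels
    blood: BloodProperties = field(default_factory=BloodProperties)
    shape_coefficients: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)  # e.g. pulm_perfusion_mmhg, myocardium

    def __post_init__(self):
        if self.hr_bpm <= 0:
            raise ConfigError("heart rate must be positive")
        missing = [c for c in CHAMBER_ORDER if c not in self.chambers]
        if missing:
            raise ConfigError(f"missing chambers: {missing}")
        missing = [v for v in VALVE_ORDER if v not in self.valves]
        if missing:
            raise ConfigError(f"missing valves: {missing}")
        if not self.organs:
            raise ConfigError("at least one systemic organ compartment required")

    @property
    def period(self):
        return 60.0 / self.hr_bpm

    @property
    def organ_names(self):
        return tuple(self.organs)

    def copy(self):
        return NetworkConfig(
            hr_bpm=self.hr_bpm,
            chambers={k: replace(v) for k, v in self.chambers.items()},
            valves={k: replace(v) for k, v in self.valves.items()},
            organs={k: replace(v) for k, v in self.organs.items()},
            vessels=GreatVessels(
                *(replace(v) for v in self.vessels.as_tuple()),
                R_pulm_bed=self.vessels.R_pulm_bed,
            ),
            blood=replace(self.blood),
            shape_coefficients=dict(self.shape_coefficients),
            meta=dict(self.meta),
        )

    def shape_coeff(self, chamber):
        shape = self.chambers[chamber].shape
        return self.shape_coefficients.get(shape, SHAPE_COEFFICIENTS[shape])


@dataclass(frozen=True)
class StateLayout:
    """Index map of the packed state vector."""

    n_organs: int

    @property
    def n_states(self):
        return 16 + 2 * self.n_organs

    # chamber volumes 0..3 in CHAMBER_ORDER; vessel volumes 4..7
    chamber = slice(0, 4)
    vessel = slice(4, 8)

    @property
    def organ_art(self):
        return slice(8, 8 + self.n_organs)

    @property
    def organ_ven(self):
        return slice(8 + self.n_organs, 8 + 2 * self.n_organs)

    @property
    def valve_q(self):
        n = 8 + 2 * self.n_organs
        return slice(n, n + 4)

    @property
    def valve_zeta(self):
        n = 12 + 2 * self.n_organs
        return slice(n, n + 4)

    @property
    def volume_states(self):
        """Indices of all volume states (chambers + vessels + organs)."""
        return slice(0, 8 + 2 * self.n_organs)


# --------------------------------------------------------------------------
# elementary operations


def _activation(t_wrapped, tau1, tau2, m1, m2):
    g1 = (t_wrapped / tau1) ** m1
    g2 = (t_wrapped / tau2) ** m2
    return (g1 / (1.0 + g1)) / (1.0 + g2)


def elastance_scale(ch: ChamberParams, hr_bpm, n_grid=100_001):
    """Scaling factor k such that max over the beat of E(t) equals Emax."""
    T = 60.0 / hr_bpm
    t = np.linspace(0.0, T, n_grid, endpoint=False)
    peak = float(np.max(_activation(t, ch.tau1, ch.tau2, ch.m1, ch.m2)))
    if peak <= 0:
        raise ParameterError(f"{ch.name}: activation never rises above zero")
    return (ch.Emax - ch.Emin) / peak


def elastance_at(t, ch: ChamberParams, hr_bpm, k=None):
    """Time-varying elastance E(t) (mmHg/ml) at time t within the beat.

    ``t - t_onset`` is wrapped modulo the period, so atrial activation set
    with a negative onset lands late in the beat without branching.
    """
    if k is None:
        k = elastance_scale(ch, hr_bpm)
    T = 60.0 / hr_bpm
    tw = np.mod(np.asarray(t, dtype=float) - ch.t_onset, T)
    return k * _activation(tw, ch.tau1, ch.tau2, ch.m1, ch.m2) + ch.Emin


def chamber_pressure(V, E, Vp0):
    """p = E * (V - Vp0); negative values are admissible (suction)."""
    return E * (np.asarray(V, dtype=float) - Vp0)


def valve_step(v: ValveParams, dp, zeta, q, R_series=0.0):
    """Time derivatives (dzeta/dt, dq/dt) of one valve branch.

    ``dp`` is the full transvalvular pressure gradient (mmHg).  The flow
    obeys ``L(zeta) dq/dt = dp - R_series q - B(zeta) q|q|`` with
    ``B = rho/(2 Aeff^2)`` and ``L = rho l_eff/Aeff``; the opening fraction
    relaxes at a rate proportional to the gradient.
    """
    zeta = min(max(zeta, 0.0), 1.0)
    aeff = v.A_closed + (v.A_open - v.A_closed) * zeta
    if aeff < _AEFF_FLOOR:
        aeff = _AEFF_FLOOR
    B = v.B_coeff / (aeff * aeff)
    L = v.L_coeff / aeff
    dq = (dp - R_series * q - B * q * abs(q)) / L
    if dp > 0:
        dzeta = v.K_open * dp * (1.0 - zeta)
    else:
        dzeta = v.K_close * dp * zeta
    return dzeta, dq


# --------------------------------------------------------------------------
# parameter packing (shared by the python rhs and the compiled kernel)


@dataclass
class PackedParams:
    T: float
    n_organs: int
    # chambers, in CHAMBER_ORDER
    Emax: np.ndarray
    Emin: np.ndarray
    kscale: np.ndarray
    tau1: np.ndarray
    tau2: np.ndarray
    m1: np.ndarray
    m2: np.ndarray
    t_onset: np.ndarray
    Vp0: np.ndarray
    vwall: np.ndarray
    kshape: np.ndarray
    # valves, in VALVE_ORDER
    A_open: np.ndarray
    A_closed: np.ndarray
    K_open: np.ndarray
    K_close: np.ndarray
    B_coeff: np.ndarray
    L_coeff: np.ndarray
    R_char: np.ndarray
    # vessels: aorta, vena cava, pulm art, pulm ven
    C_vessel: np.ndarray
    R_vc: float
    R_pb: float
    R_pv: float
    # organs
    Rart: np.ndarray
    Rvb: np.ndarray
    Rven: np.ndarray
    Cart: np.ndarray
    Cven: np.ndarray


def pack_params(net: NetworkConfig) -> PackedParams:
    ch = [net.chambers[c] for c in CHAMBER_ORDER]
    va = [net.valves[v] for v in VALVE_ORDER]
    og = list(net.organs.values())
    ves = net.vessels
    arr = lambda xs: np.asarray(xs, dtype=float)
    return PackedParams(
        T=net.period,
        n_organs=len(og),
        Emax=arr([c.Emax for c in ch]),
        Emin=arr([c.Emin for c in ch]),
        kscale=arr([elastance_scale(c, net.hr_bpm) for c in ch]),
        tau1=arr([c.tau1 for c in ch]),
        tau2=arr([c.tau2 for c in ch]),
        m1=arr([c.m1 for c in ch]),
        m2=arr([c.m2 for c in ch]),
        t_onset=arr([c.t_onset for c in ch]),
        Vp0=arr([c.Vp0 for c in ch]),
        vwall=arr([c.vwall for c in ch]),
        kshape=arr([net.shape_coeff(c.name) for c in ch]),
        A_open=arr([v.A_open for v in va]),
        A_closed=arr([v.A_closed for v in va]),
        K_open=arr([v.K_open for v in va]),
        K_close=arr([v.K_close for v in va]),
        B_coeff=arr([v.B_coeff for v in va]),
        L_coeff=arr([v.L_coeff for v in va]),
        R_char=arr([ves.aorta.R, ves.pulm_art.R, 0.0, 0.0]),
        C_vessel=arr([v.C for v in ves.as_tuple()]),
        R_vc=ves.vena_cava.R,
        R_pb=ves.R_pulm_bed,
        R_pv=ves.pulm_ven.R,
        Rart=arr([o.Rart for o in og]),
        Rvb=arr([o.Rvb for o in og]),
        Rven=arr([o.Rven for o in og]),
        Cart=arr([o.Cart for o in og]),
        Cven=arr([o.Cven for o in og]),
    )


# --------------------------------------------------------------------------
# ODE assembly (reference python path; the compiled kernel mirrors this)


def assemble_odes(net: NetworkConfig):
    """Return (rhs, layout) for the closed loop.

    ``rhs(t, y)`` implements mass balance at every storage node, compliance
    and elastance pressure relations, resistive flows, and the valve
    dynamics.  The sum of all volume-state derivatives is zero by
    construction (closed loop).
    """
    p = pack_params(net)
    layout = StateLayout(p.n_organs)
    n = p.n_organs
    va = [net.valves[v] for v in VALVE_ORDER]

    def rhs(t, y):
        dy = np.zeros_like(y)
        E = np.empty(4)
        for i in range(4):
            tw = (t - p.t_onset[i]) % p.T
            E[i] = p.kscale[i] * _activation(tw, p.tau1[i], p.tau2[i], p.m1[i], p.m2[i]) + p.Emin[i]
        pch = E * (y[0:4] - p.Vp0)
        p_ao = y[4] / p.C_vessel[0]
        p_vc = y[5] / p.C_vessel[1]
        p_pa = y[6] / p.C_vessel[2]
        p_pv = y[7] / p.C_vessel[3]

        q = y[layout.valve_q]
        zeta = y[layout.valve_zeta]
        up = np.array([pch[0], pch[1], pch[2], pch[3]])
        down = np.array([p_ao, p_pa, pch[0], pch[1]])
        dzeta = np.empty(4)
        dq = np.empty(4)
        for i in range(4):
            dzeta[i], dq[i] = valve_step(va[i], up[i] - down[i], zeta[i], q[i], p.R_char[i])

        p_art = y[layout.organ_art] / p.Cart
        p_ven = y[layout.organ_ven] / p.Cven
        q_in = (p_ao - p_art) / p.Rart
        q_vb = (p_art - p_ven) / p.Rvb
        q_out = (p_ven - p_vc) / p.Rven
        q_vcra = (p_vc - pch[3]) / p.R_vc
        q_papv = (p_pa - p_pv) / p.R_pb
        q_pvla = (p_pv - pch[2]) / p.R_pv

        dy[0] = q[2] - q[0]  # LV: mitral in, aortic out
        dy[1] = q[3] - q[1]  # RV
        dy[2] = q_pvla - q[2]  # LA
        dy[3] = q_vcra - q[3]  # RA
        dy[4] = q[0] - np.sum(q_in)  # aorta
        dy[5] = np.sum(q_out) - q_vcra  # vena cava
        dy[6] = q[1] - q_papv  # pulmonary arteries
        dy[7] = q_papv - q_pvla  # pulmonary veins
        dy[8 : 8 + n] = q_in - q_vb
        dy[8 + n : 8 + 2 * n] = q_vb - q_out
        dy[layout.valve_q] = dq
        dy[layout.valve_zeta] = dzeta
        return dy

    return rhs, layout


def default_initial_state(net: NetworkConfig, pressures=None):
    """A physiologically plausible cold-start state.

    ``pressures`` may override the nominal node pressures
    (ao, vc, pa, pv, art, ven, chamber filling).
    """
    pr = {"ao": 80.0, "vc": 6.0, "pa": 15.0, "pv": 8.0, "art": 76.0,
          "ven": 8.0, "fill": 7.0}
    if pressures:
        pr.update(pressures)
    p = pack_params(net)
    layout = StateLayout(p.n_organs)
    y = np.zeros(layout.n_states)
    # chambers at their diastolic filling volume
    for i, name in enumerate(CHAMBER_ORDER):
        fill = pr["fill"] if name in ("LV", "RV") else 0.6 * pr["fill"]
        y[i] = p.Vp0[i] + fill / p.Emin[i]
    y[4:8] = np.array([pr["ao"], pr["vc"], pr["pa"], pr["pv"]]) * p.C_vessel
    y[layout.organ_art] = pr["art"] * p.Cart
    y[layout.organ_ven] = pr["ven"] * p.Cven
    y[layout.valve_zeta] = 0.0
    return y


# --------------------------------------------------------------------------
# beat records


class BeatRecord:
    """Sampled waveforms and exact beat-mean aggregates for one heartbeat.

    Waveform samples cover one period [0, T].  Beat means (``acc``) are
    accumulated at every integrator step, so quantities such as CO and MAP
    are insensitive to the sampling stride.
    """

    def __init__(self, net: NetworkConfig, t, states, acc, y_end, n_beat=None):
        self.net = net
        self.time = np.asarray(t)
        self.states = np.asarray(states)
        self.layout = StateLayout(len(net.organs))
        self.acc = acc  # dict of beat means, or None
        self.y_end = np.asarray(y_end)
        self.n_beat = n_beat
        self.params = pack_params(net)
        self._E_cache = None

    # --- basic accessors -------------------------------------------------
    @property
    def period(self):
        return self.net.period

    @property
    def hr_bpm(self):
        return self.net.hr_bpm

    def _chamber_index(self, chamber):
        return CHAMBER_ORDER.index(chamber)

    def chamber_shape(self, chamber):
        return self.net.chambers[chamber].shape

    def chamber_vwall(self, chamber):
        return self.net.chambers[chamber].vwall

    def chamber_volume(self, chamber):
        return self.states[:, self._chamber_index(chamber)]

    def chamber_elastance(self, chamber):
        if self._E_cache is None:
            self._E_cache = {}
        if chamber not in self._E_cache:
            i = self._chamber_index(chamber)
            ch = self.net.chambers[chamber]
            self._E_cache[chamber] = elastance_at(
                self.time, ch, self.hr_bpm, k=self.params.kscale[i]
            )
        return self._E_cache[chamber]

    def chamber_pressure(self, chamber):
        i = self._chamber_index(chamber)
        return self.chamber_elastance(chamber) * (
            self.states[:, i] - self.params.Vp0[i]
        )

    def vessel_pressure(self, vessel):
        names = ("aorta", "vena_cava", "pulm_art", "pulm_ven")
        i = names.index(vessel)
        return self.states[:, 4 + i] / self.params.C_vessel[i]

    def organ_pressure(self, organ, side="art"):
        j = list(self.net.organs).index(organ)
        n = self.params.n_organs
        if side == "art":
            return self.states[:, 8 + j] / self.params.Cart[j]
        return self.states[:, 8 + n + j] / self.params.Cven[j]

    def valve_flow(self, valve):
        i = VALVE_ORDER.index(valve)
        return self.states[:, self.layout.valve_q][:, i]

    def valve_opening(self, valve):
        i = VALVE_ORDER.index(valve)
        return self.states[:, self.layout.valve_zeta][:, i]

    def venous_return_flow(self):
        return (self.vessel_pressure("vena_cava") - self.chamber_pressure("RA")) / self.params.R_vc

    def pulm_venous_flow(self):
        return (self.vessel_pressure("pulm_ven") - self.chamber_pressure("LA")) / self.params.R_pv

    def chamber_radius(self, chamber):
        i = self._chamber_index(chamber)
        return lumen_radius(self.chamber_shape(chamber), self.chamber_volume(chamber),
                            self.net.shape_coefficients)

    def chamber_thickness(self, chamber):
        r = self.chamber_radius(chamber)
        return wall_thickness(self.chamber_shape(chamber), r,
                              self.chamber_vwall(chamber), self.net.shape_coefficients)

    # --- beat-mean aggregates --------------------------------------------
    def _acc_get(self, key, idx=None):
        if self.acc is None:
            return None
        v = self.acc.get(key)
        if v is None:
            return None
        return float(v[idx]) if idx is not None else float(v)

    def mean_state(self):
        if self.acc is not None:
            return self.acc["y_mean"]
        return np.trapezoid(self.states, self.time, axis=0) / (self.time[-1] - self.time[0])

    def mean_radius(self, chamber):
        return self._acc_get("r_mean", self._chamber_index(chamber))

    def mean_thickness(self, chamber):
        return self._acc_get("h_mean", self._chamber_index(chamber))

    def mean_chamber_pressure(self, chamber):
        v = self._acc_get("p_ch_mean", self._chamber_index(chamber))
        if v is not None:
            return v
        p = self.chamber_pressure(chamber)
        return float(np.trapezoid(p, self.time) / (self.time[-1] - self.time[0]))

    def mean_laplace_stress(self, chamber):
        return self._acc_get("sf_mean", self._chamber_index(chamber))

    def mean_valve_flow(self, valve, absolute=False):
        i = VALVE_ORDER.index(valve)
        key = "q_abs_mean" if absolute else "q_mean"
        v = self._acc_get(key, i)
        if v is not None:
            return v
        q = self.valve_flow(valve)
        if absolute:
            q = np.abs(q)
        return float(np.trapezoid(q, self.time) / (self.time[-1] - self.time[0]))

    def mean_inlet_flow(self, chamber):
        """Beat-mean inflow (ml/s): valve flow for the ventricles, lumped
        venous inflow for the atria."""
        if chamber == "LV":
            return self.mean_valve_flow("MV")
        if chamber == "RV":
            return self.mean_valve_flow("TV")
        key = {"LA": "q_pvla_mean", "RA": "q_vcra_mean"}[chamber]
        v = self._acc_get(key)
        if v is not None:
            return v
        q = self.pulm_venous_flow() if chamber == "LA" else self.venous_return_flow()
        return float(np.trapezoid(q, self.time) / (self.time[-1] - self.time[0]))

    def mean_abs_outlet_flow(self, chamber):
        outlet = {"LV": "AV", "RV": "PV", "LA": "MV", "RA": "TV"}[chamber]
        return self.mean_valve_flow(outlet, absolute=True)

    def mean_aortic_pressure(self):
        if self.acc is not None:
            return float(self.acc["y_mean"][4] / self.params.C_vessel[0])
        p = self.vessel_pressure("aorta")
        return float(np.trapezoid(p, self.time) / (self.time[-1] - self.time[0]))

    def cardiac_output(self):
        """Beat-mean aortic valve flow, L/min."""
        return self.mean_valve_flow("AV") * 60.0 / 1000.0

    def total_volume(self):
        """Instantaneous total blood volume (ml) at the final state."""
        return float(np.sum(self.y_end[self.layout.volume_states]))

    def mean_total_volume(self):
        return float(np.sum(self.mean_state()[self.layout.volume_states]))

    # --- export -----------------------------------------------------------
    def waveforms(self):
        """All signals as a DataFrame, one row per sample, columns
        ``<element>.<signal>``."""
        import pandas as pd

        cols = {"t_s": self.time}
        for c in CHAMBER_ORDER:
            cols[f"{c}.p_mmHg"] = self.chamber_pressure(c)
            cols[f"{c}.V_ml"] = self.chamber_volume(c)
            cols[f"{c}.r_cm"] = self.chamber_radius(c)
            cols[f"{c}.h_cm"] = self.chamber_thickness(c)
        for v in VALVE_ORDER:
            cols[f"{v}.q_ml_s"] = self.valve_flow(v)
            cols[f"{v}.zeta"] = self.valve_opening(v)
        for name in ("aorta", "vena_cava", "pulm_art", "pulm_ven"):
            cols[f"{name}.p_mmHg"] = self.vessel_pressure(name)
        for organ in self.net.organs:
            cols[f"{organ}.p_art_mmHg"] = self.organ_pressure(organ, "art")
            cols[f"{organ}.p_ven_mmHg"] = self.organ_pressure(organ, "ven")
        return pd.DataFrame(cols)

    def to_csv(self, path):
        self.waveforms().to_csv(path, index=False)

    def summary(self):
        from . import clinical

        return clinical.beat_metrics(self)


# --------------------------------------------------------------------------
# integration


def _acc_to_dict(acc_vec, layout: StateLayout):
    nys = layout.n_states
    d = {}
    d["y_mean"] = acc_vec[:nys].copy()
    i = nys
    d["p_ch_mean"] = acc_vec[i : i + 4].copy(); i += 4
    d["q_mean"] = acc_vec[i : i + 4].copy(); i += 4
    d["q_abs_mean"] = acc_vec[i : i + 4].copy(); i += 4
    d["q_vcra_mean"] = float(acc_vec[i]); i += 1
    d["q_pvla_mean"] = float(acc_vec[i]); i += 1
    d["r_mean"] = acc_vec[i : i + 4].copy(); i += 4
    d["h_mean"] = acc_vec[i : i + 4].copy(); i += 4
    d["sf_mean"] = acc_vec[i : i + 4].copy(); i += 4
    return d


def _elastance_grid(p: PackedParams, n_steps, dt):
    """E(t) for all four chambers on the half-step grid 0, dt/2, dt, ..."""
    t = np.arange(2 * n_steps + 1) * (0.5 * dt)
    E = np.empty((4, t.size))
    for i in range(4):
        tw = np.mod(t - p.t_onset[i], p.T)
        E[i] = p.kscale[i] * _activation(tw, p.tau1[i], p.tau2[i], p.m1[i], p.m2[i]) + p.Emin[i]
    return E


def simulate_beat(net: NetworkConfig, y0, dt=1e-4, sample_every=5, backend="auto"):
    """Integrate exactly one beat; return a :class:`BeatRecord`.

    backend: "auto" (compiled kernel if numba is importable), "python"
    (same fixed-step RK4 in numpy), or "scipy" (adaptive LSODA; used as an
    independent cross-check).
    """
    p = pack_params(net)
    layout = StateLayout(p.n_organs)
    y0 = np.asarray(y0, dtype=float)
    if y0.size != layout.n_states:
        raise ConfigError(
            f"state size {y0.size} != expected {layout.n_states} for {p.n_organs} organs"
        )
    n_steps = int(round(p.T / dt))
    if backend == "scipy":
        return _simulate_beat_scipy(net, y0, dt, sample_every)

    from ._kernel import get_kernel

    kernel = get_kernel(backend)
    n_samples = (n_steps + sample_every - 1) // sample_every + 1
    samples = np.empty((n_samples, 1 + layout.n_states))
    acc = np.zeros(layout.n_states + 26)
    y = y0.copy()
    Egrid = _elastance_grid(p, n_steps, dt)
    kernel(
        y, n_steps, dt, sample_every, Egrid,
        p.Vp0, p.kshape, p.vwall,
        p.A_open, p.A_closed, p.K_open, p.K_close, p.B_coeff, p.L_coeff, p.R_char,
        p.C_vessel, p.R_vc, p.R_pb, p.R_pv,
        p.Rart, p.Rvb, p.Rven, p.Cart, p.Cven,
        samples, acc,
    )
    if not np.all(np.isfinite(y)):
        raise IntegrationError("non-finite state after beat integration")
    samples[-1, 0] = p.T
    samples[-1, 1:] = y
    return BeatRecord(net, samples[:, 0], samples[:, 1:], _acc_to_dict(acc, layout), y)


def _simulate_beat_scipy(net, y0, dt, sample_every, method="LSODA",
                         rtol=1e-6, atol=1e-8):
    from scipy.integrate import solve_ivp

    p = pack_params(net)
    layout = StateLayout(p.n_organs)
    rhs, _ = assemble_odes(net)
    t_eval = np.arange(0.0, p.T + 0.5 * dt * sample_every, dt * sample_every)
    t_eval[-1] = min(t_eval[-1], p.T)
    sol = solve_ivp(rhs, (0.0, p.T), y0, method=method, rtol=rtol, atol=atol,
                    t_eval=t_eval, max_step=5e-3)
    if not sol.success:
        raise IntegrationError(f"solve_ivp failed: {sol.message}")
    states = sol.y.T
    # clamp zeta, as the kernel does
    states[:, layout.valve_zeta] = np.clip(states[:, layout.valve_zeta], 0.0, 1.0)
    return BeatRecord(net, sol.t, states, None, states[-1])


def run_to_periodic_steady_state(
    net: NetworkConfig,
    init=None,
    dt=1e-4,
    min_beats=30,
    max_beats=200,
    tol=1e-3,
    backend="auto",
):
    """Integrate beat by beat until the periodic steady state.

    Steady state is declared when the beat-mean cardiac output and mean
    aortic pressure both change by less than ``tol`` (relative) between
    consecutive beats and at least ``min_beats`` beats have been run.
    Raises :class:`ConvergenceError` otherwise.  Total blood volume is
    conserved by construction; the realised drift is checked to < 0.1%.
    """
    y = default_initial_state(net) if init is None else np.asarray(init, dtype=float).copy()
    layout = StateLayout(len(net.organs))
    v_start = float(np.sum(y[layout.volume_states]))
    prev_co = prev_map = None
    r_co = r_map = None
    beat = None
    for n in range(1, max_beats + 1):
        beat = simulate_beat(net, y, dt=dt, backend=backend)
        y = beat.y_end
        co = beat.cardiac_output()
        mp = beat.mean_aortic_pressure()
        if prev_co is not None and co > 0:
            r_co = abs(co - prev_co) / abs(co)
            r_map = abs(mp - prev_map) / abs(mp)
            if n >= min_beats and r_co < tol and r_map < tol:
                beat.n_beat = n
                v_end = beat.total_volume()
                drift = abs(v_end - v_start) / v_start
                if drift > 1e-3:
                    raise IntegrationError(
                        f"blood volume drifted by {drift:.2e} over the run"
                    )
                return beat
        prev_co, prev_map = co, mp
    raise ConvergenceError(
        f"no periodic steady state within {max_beats} beats",
        residuals={"d_co": r_co, "d_map": r_map},
    )
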