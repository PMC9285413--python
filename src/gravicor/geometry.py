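"""Chamber geometry and wall-stress computations.

Each heart chamber is reduced to an idealised thin- or thick-walled shell:
the atria are spheres, the left ventricle a half ellipsoid and the right
ventricle a quarter ellipsoid, in all cases with the long semi-axis fixed at
three times the inner radius ``r``.  Lumen volume is therefore ``V =
k_shape * r**3`` with a single shape coefficient per chamber, and the wall of
myocardial volume ``vwall`` is distributed as a uniform shell of thickness
``h`` around the lumen.

Two mechanical stimuli are derived from a converged beat:

* the myofiber stress ``sigma_f`` — end-systolic meridional stress for the
  ventricles (force balance across the mid-plane of the shell), mean Laplace
  stress over the beat for the thin-walled atria; and
* the endocardial wall shear stress ``sigma_wss`` — a Poiseuille-type
  estimate ``4*mu*q/(pi*r**3)`` from the mean chamber throughflow.

These two scalars drive the growth-and-remodeling loop in
:mod:`gravicor.remodeling`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import AnalysisError, ConfigError

__all__ = [
    "SHAPE_COEFFICIENTS",
    "DYN_PER_CM2_TO_PA",
    "ChamberGeometry",
    "StressPair",
    "lumen_radius",
    "wall_thickness",
    "chamber_geometry",
    "ventricular_end_systolic_stress",
    "atrial_mean_stress",
    "chamber_wall_shear_stress",
]

#: lumen volume = k_shape * r^3 for each supported shape.  The ellipsoidal
#: coefficients assume semi-axes (r, r, 3r): a full ellipsoid has volume
#: 4/3*pi*3*r^3 = 4*pi*r^3, so the half is 2*pi*r^3 and the quarter pi*r^3.
SHAPE_COEFFICIENTS = {
    "sphere": 4.0 * np.pi / 3.0,
    "half_ellipsoid": 2.0 * np.pi,
    "quarter_ellipsoid": np.pi,
}

DYN_PER_CM2_TO_PA = 0.1
MMHG_TO_DYN_PER_CM2 = 1333.22

THIN_WALL_LIMIT = 0.1  # validity bound h/r for the atrial Laplace formula


def _shape_coefficient(shape, overrides=None):
    if overrides and shape in overrides:
        return float(overrides[shape])
    try:
        return SHAPE_COEFFICIENTS[shape]
    except KeyError:
        raise ConfigError(f"unknown chamber shape {shape!r}") from None


def lumen_radius(shape, volume_ml, shape_coefficients=None):
    """Inner radius (cm) of a chamber of the given shape and lumen volume (ml)."""
    if np.any(np.asarray(volume_ml) <= 0):
        raise ValueError("lumen volume must be positive")
    k = _shape_coefficient(shape, shape_coefficients)
    return np.cbrt(np.asarray(volume_ml, dtype=float) / k)


def wall_thickness(shape, r_cm, vwall_ml, shape_coefficients=None):
    """Uniform shell thickness h (cm) such that k*((r+h)^3 - r^3) = vwall.

    The shell equation has the closed-form positive root
    ``h = (r^3 + vwall/k)^(1/3) - r``.
    """
    r = np.asarray(r_cm, dtype=float)
    if np.any(r <= 0):
        raise ValueError("radius must be positive")
    if np.any(np.asarray(vwall_ml) <= 0):
        raise ValueError("wall volume must be positive")
    k = _shape_coefficient(shape, shape_coefficients)
    return np.cbrt(r**3 + np.asarray(vwall_ml, dtype=float) / k) - r


@dataclass
class ChamberGeometry:
    """Instantaneous shell geometry of one chamber."""

    shape: str
    r: float  # inner radius, cm
    h: float  # wall thickness, cm
    lumen_volume: float  # ml
    vwall: float  # ml
    k_shape: float

    def __post_init__(self):
        if self.r <= 0 or self.h <= 0:
            raise ValueError("radius and thickness must be positive")
        shell = self.k_shape * ((self.r + self.h) ** 3 - self.r**3)
        if abs(shell - self.vwall) > 1e-9 * max(self.vwall, 1.0):
            raise ValueError("inconsistent shell: k*((r+h)^3-r^3) != vwall")


def chamber_geometry(shape, lumen_volume_ml, vwall_ml, shape_coefficients=None):
    """Build a consistent :class:`ChamberGeometry` from volumes."""
    k = _shape_coefficient(shape, shape_coefficients)
    r = float(lumen_radius(shape, lumen_volume_ml, shape_coefficients))
    h = float(wall_thickness(shape, r, vwall_ml, shape_coefficients))
    return ChamberGeometry(shape, r, h, float(lumen_volume_ml), float(vwall_ml), k)


@dataclass
class StressPair:
    """The two remodeling stimuli of one chamber for one beat.

    ``sigma_f`` is in mmHg.  ``sigma_wss`` is stored in Pa
    (1 dyn/cm^2 = 0.1 Pa); exports convert as needed.
    """

    sigma_f: float
    sigma_wss: float
    convention: str  # "end_systolic" (ventricles) or "beat_mean" (atria)

    def __post_init__(self):
        if not (np.isfinite(self.sigma_f) and np.isfinite(self.sigma_wss)):
            raise ValueError("stresses must be finite")


def meridional_stress(p_mmhg, r_cm, h_cm):
    """Mid-plane meridional wall stress (mmHg) of a pressurised shell.

    Clinical form ``sigma = p*r / (2*h*(1 + h/(2*r)))``; algebraically
    identical to the force balance ``sigma*pi*(Ro^2 - Ri^2) = p*pi*Ri^2``
    with Ro = r + h.
    """
    return p_mmhg * r_cm / (2.0 * h_cm * (1.0 + h_cm / (2.0 * r_cm)))


def laplace_sphere_stress(p_mmhg, r_cm, h_cm):
    """Thin-walled sphere Laplace stress ``p*r/(2*h)`` (mmHg)."""
    return p_mmhg * r_cm / (2.0 * h_cm)


def _end_systole(time, q_out, min_fraction=0.02):
    """Time of outlet-valve closure: first downward zero crossing of the
    outlet flow after its peak.  Returns (index, interpolation weight)."""
    q = np.asarray(q_out, dtype=float)
    peak = int(np.argmax(q))
    if q[peak] <= 0 or q[peak] < min_fraction:
        raise AnalysisError("outlet valve never opened; end-systole undefined")
    after = np.nonzero(q[peak:-1] * q[peak + 1 :] <= 0)[0]
    after = after[q[peak + after] > 0]
    if after.size == 0:
        raise AnalysisError("no outlet-valve closure found in beat")
    i = peak + int(after[0])
    # linear interpolation weight of the zero crossing within [i, i+1]
    denom = q[i] - q[i + 1]
    w = q[i] / denom if denom != 0 else 0.0
    return i, w


def _interp(series, i, w):
    s = np.asarray(series, dtype=float)
    return (1.0 - w) * s[i] + w * s[i + 1]


def ventricular_end_systolic_stress(beat, chamber, shape_coefficients=None):
    """End-systolic myofiber stress (mmHg) of a ventricle.

    End-systole is the instant the chamber's outlet valve flow first crosses
    zero from positive after ejection (valve closure).  Pressure, radius and
    thickness are interpolated at that instant.
    """
    if chamber not in ("LV", "RV"):
        raise ValueError("ventricular stress is defined for LV and RV only")
    outlet = {"LV": "AV", "RV": "PV"}[chamber]
    q = beat.valve_flow(outlet)
    i, w = _end_systole(beat.time, q)
    p_es = _interp(beat.chamber_pressure(chamber), i, w)
    v_es = _interp(beat.chamber_volume(chamber), i, w)
    shape = beat.chamber_shape(chamber)
    vwall = beat.chamber_vwall(chamber)
    r = float(lumen_radius(shape, v_es, shape_coefficients))
    h = float(wall_thickness(shape, r, vwall, shape_coefficients))
    return meridional_stress(p_es, r, h)


def atrial_mean_stress(beat, chamber, shape_coefficients=None):
    """Beat-averaged Laplace stress (mmHg) of a thin-walled atrium."""
    if chamber not in ("LA", "RA"):
        raise ValueError("atrial stress is defined for LA and RA only")
    shape = beat.chamber_shape(chamber)
    vwall = beat.chamber_vwall(chamber)
    v = beat.chamber_volume(chamber)
    r = lumen_radius(shape, v, shape_coefficients)
    h = wall_thickness(shape, r, vwall, shape_coefficients)
    if np.any(h / r >= THIN_WALL_LIMIT):
        warnings.warn(
            f"{chamber}: h/r >= {THIN_WALL_LIMIT} during the beat; the "
            "thin-wall Laplace formula is outside its validity range",
            RuntimeWarning,
            stacklevel=2,
        )
    mean = beat.mean_laplace_stress(chamber)
    if mean is not None:
        return mean
    p = beat.chamber_pressure(chamber)
    t = beat.time
    return float(np.trapezoid(p * r / (2.0 * h), t) / (t[-1] - t[0]))


def chamber_wall_shear_stress(beat, chamber, mu_poise, shape_coefficients=None):
    """Poiseuille-type endocardial wall shear stress (dyn/cm^2).

    ``sigma_wss = 4*mu*q_chamber / (pi * rbar^3)`` with ``q_chamber`` the
    average of the beat-mean inlet flow and the beat-mean absolute outlet
    flow, and ``rbar`` the beat-mean inner radius.
    """
    q_in = beat.mean_inlet_flow(chamber)
    q_out_abs = beat.mean_abs_outlet_flow(chamber)
    q_chamber = 0.5 * (q_in + q_out_abs)
    rbar = beat.mean_radius(chamber)
    if rbar is None:
        v = beat.chamber_volume(chamber)
        r = lumen_radius(beat.chamber_shape(chamber), v, shape_coefficients)
        t = beat.time
        rbar = float(np.trapezoid(r, t) / (t[-1] - t[0]))
    return 4.0 * mu_poise * q_chamber / (np.pi * rbar**3)
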