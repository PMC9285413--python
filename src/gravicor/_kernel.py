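"""Fixed-step RK4 integrator for the closed-loop network.

This mirrors :func:`gravicor.hemo.assemble_odes` exactly (a test asserts
agreement with the adaptive scipy path) but runs the whole beat inside one
compiled loop.  Elastance waveforms depend on time only, so they are
pre-evaluated on the half-step grid and passed in as ``Egrid``.

The explicit scheme is stable here because (a) every storage node has an RC
time constant well above the step, and (b) the valve law uses an inertance
scaling L ~ 1/Aeff together with a finite leak area, which bounds the flow
relaxation rate q/(2*l_eff*Aeff) near closure.
"""

from __future__ import annotations

import numpy as np

_AEFF_FLOOR = 1e-10


def _make_rhs():
    def rhs(t_idx, y, Egrid, Vp0, kshape, vwall,
            A_open, A_closed, K_open, K_close, B_coeff, L_coeff, R_char,
            C_vessel, R_vc, R_pb, R_pv,
            Rart, Rvb, Rven, Cart, Cven, dy, pch):
        n = Rart.shape[0]
        nys = 16 + 2 * n
        for i in range(4):
            pch[i] = Egrid[i, t_idx] * (y[i] - Vp0[i])
        p_ao = y[4] / C_vessel[0]
        p_vc = y[5] / C_vessel[1]
        p_pa = y[6] / C_vessel[2]
        p_pv = y[7] / C_vessel[3]

        iq = 8 + 2 * n
        iz = iq + 4
        sum_qin = 0.0
        sum_qout = 0.0
        for j in range(n):
            pa_j = y[8 + j] / Cart[j]
            pv_j = y[8 + n + j] / Cven[j]
            qa = (p_ao - pa_j) / Rart[j]
            qb = (pa_j - pv_j) / Rvb[j]
            qv = (pv_j - p_vc) / Rven[j]
            dy[8 + j] = qa - qb
            dy[8 + n + j] = qb - qv
            sum_qin += qa
            sum_qout += qv
        q_vcra = (p_vc - pch[3]) / R_vc
        q_papv = (p_pa - p_pv) / R_pb
        q_pvla = (p_pv - pch[2]) / R_pv

        # valves: AV (LV->ao), PV (RV->pa), MV (LA->LV), TV (RA->RV)
        for i in range(4):
            if i == 0:
                dp = pch[0] - p_ao
            elif i == 1:
                dp = pch[1] - p_pa
            elif i == 2:
                dp = pch[2] - pch[0]
            else:
                dp = pch[3] - pch[1]
            z = y[iz + i]
            if z < 0.0:
                z = 0.0
            elif z > 1.0:
                z = 1.0
            aeff = A_closed[i] + (A_open[i] - A_closed[i]) * z
            if aeff < _AEFF_FLOOR:
                aeff = _AEFF_FLOOR
            q = y[iq + i]
            B = B_coeff[i] / (aeff * aeff)
            L = L_coeff[i] / aeff
            dy[iq + i] = (dp - R_char[i] * q - B * q * abs(q)) / L
            if dp > 0.0:
                dy[iz + i] = K_open[i] * dp * (1.0 - z)
            else:
                dy[iz + i] = K_close[i] * dp * z

        qAV = y[iq + 0]
        qPV = y[iq + 1]
        qMV = y[iq + 2]
        qTV = y[iq + 3]
        dy[0] = qMV - qAV
        dy[1] = qTV - qPV
        dy[2] = q_pvla - qMV
        dy[3] = q_vcra - qTV
        dy[4] = qAV - sum_qin
        dy[5] = sum_qout - q_vcra
        dy[6] = qPV - q_papv
        dy[7] = q_papv - q_pvla
        return q_vcra, q_pvla

    return rhs


def _make_kernel(rhs):
    def rk4_beat(y, n_steps, dt, stride, Egrid,
                 Vp0, kshape, vwall,
                 A_open, A_closed, K_open, K_close, B_coeff, L_coeff, R_char,
                 C_vessel, R_vc, R_pb, R_pv,
                 Rart, Rvb, Rven, Cart, Cven,
                 samples, acc):
        n = Rart.shape[0]
        nys = 16 + 2 * n
        iq = 8 + 2 * n
        iz = iq + 4
        k1 = np.empty(nys)
        k2 = np.empty(nys)
        k3 = np.empty(nys)
        k4 = np.empty(nys)
        yt = np.empty(nys)
        pch = np.empty(4)
        pch_t = np.empty(4)
        for m in range(acc.shape[0]):
            acc[m] = 0.0
        row = 0
        half = 0.5 * dt
        sixth = dt / 6.0
        for step in range(n_steps):
            t = step * dt
            if step % stride == 0:
                samples[row, 0] = t
                for m in range(nys):
                    samples[row, 1 + m] = y[m]
                row += 1
            q_vcra, q_pvla = rhs(2 * step, y, Egrid, Vp0, kshape, vwall,
                                 A_open, A_closed, K_open, K_close,
                                 B_coeff, L_coeff, R_char,
                                 C_vessel, R_vc, R_pb, R_pv,
                                 Rart, Rvb, Rven, Cart, Cven, k1, pch)
            # accumulate beat means at the left endpoint (the beat is
            # periodic at steady state, so this equals the trapezoid rule)
            for m in range(nys):
                acc[m] += y[m]
            for i in range(4):
                acc[nys + i] += pch[i]
                acc[nys + 4 + i] += y[iq + i]
                acc[nys + 8 + i] += abs(y[iq + i])
            acc[nys + 12] += q_vcra
            acc[nys + 13] += q_pvla
            for i in range(4):
                r = (y[i] / kshape[i]) ** (1.0 / 3.0)
                h = (y[i] / kshape[i] + vwall[i] / kshape[i]) ** (1.0 / 3.0) - r
                acc[nys + 14 + i] += r
                acc[nys + 18 + i] += h
                acc[nys + 22 + i] += pch[i] * r / (2.0 * h)

            for m in range(nys):
                yt[m] = y[m] + half * k1[m]
            rhs(2 * step + 1, yt, Egrid, Vp0, kshape, vwall,
                A_open, A_closed, K_open, K_close, B_coeff, L_coeff, R_char,
                C_vessel, R_vc, R_pb, R_pv,
                Rart, Rvb, Rven, Cart, Cven, k2, pch_t)
            for m in range(nys):
                yt[m] = y[m] + half * k2[m]
            rhs(2 * step + 1, yt, Egrid, Vp0, kshape, vwall,
                A_open, A_closed, K_open, K_close, B_coeff, L_coeff, R_char,
                C_vessel, R_vc, R_pb, R_pv,
                Rart, Rvb, Rven, Cart, Cven, k3, pch_t)
            for m in range(nys):
                yt[m] = y[m] + dt * k3[m]
            rhs(2 * step + 2, yt, Egrid, Vp0, kshape, vwall,
                A_open, A_closed, K_open, K_close, B_coeff, L_coeff, R_char,
                C_vessel, R_vc, R_pb, R_pv,
                Rart, Rvb, Rven, Cart, Cven, k4, pch_t)
            for m in range(nys):
                y[m] += sixth * (k1[m] + 2.0 * (k2[m] + k3[m]) + k4[m])
            for i in range(4):
                if y[iz + i] < 0.0:
                    y[iz + i] = 0.0
                elif y[iz + i] > 1.0:
                    y[iz + i] = 1.0
        inv = 1.0 / n_steps
        for m in range(acc.shape[0]):
            acc[m] *= inv

    return rk4_beat


_rhs_py = _make_rhs()
_kernel_py = _make_kernel(_rhs_py)

try:  # compiled path
    import numba

    _rhs_nb = numba.njit(cache=True, fastmath=False)(_make_rhs())
    _kernel_nb = numba.njit(cache=True, fastmath=False)(_make_kernel(_rhs_nb))
except Exception:  # pragma: no cover - numba always present in practice
    _rhs_nb = None
    _kernel_nb = None


def get_kernel(backend="auto"):
    if backend == "python":
        return _kernel_py
    if backend in ("auto", "numba"):
        if _kernel_nb is not None:
            return _kernel_nb
        if backend == "numba":
            raise ImportError("numba is not available")
        return _kernel_py
    raise ValueError(f"unknown backend {backend!r}")
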