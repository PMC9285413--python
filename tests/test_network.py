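"""ODE assembly, conservation and integrator cross-checks."""

import numpy as np
import pytest

from gravicor import config, hemo
from gravicor.hemo import StateLayout, assemble_odes, default_initial_state, simulate_beat


@pytest.fixture(scope="module")
def npc_net():
    return config.build_npc_network()


class TestAssembly:
    def test_volume_conservation_of_rhs(self, npc_net):
        """Sum of all storage-node derivatives vanishes at arbitrary states."""
        rhs, layout = assemble_odes(npc_net)
        rng = np.random.default_rng(0)
        y0 = default_initial_state(npc_net)
        for t in (0.0, 0.21, 0.63):
            y = y0 * rng.uniform(0.8, 1.2, size=y0.size)
            dy = rhs(t, y)
            assert np.sum(dy[layout.volume_states]) == pytest.approx(0.0, abs=1e-9)

    def test_removing_an_organ_shrinks_state_by_two(self, npc_net):
        net = npc_net.copy()
        del net.organs["uterus"]
        _, layout = assemble_odes(net)
        _, full_layout = assemble_odes(npc_net)
        assert full_layout.n_states - layout.n_states == 2

    def test_rc_ejection_decay_closed_form(self):
        """A constant-elastance chamber discharging through a resistance into
        a compliance relaxes with the analytic two-compartment solution."""
        from scipy.integrate import solve_ivp

        E, C, R = 1.5, 2.0, 0.1

        def rhs(t, y):
            q = (hemo.chamber_pressure(y[0], E, 0.0) - y[1] / C) / R
            return [-q, q]

        y0 = [60.0, 40.0]
        sol = solve_ivp(rhs, (0, 1.0), y0, rtol=1e-10, atol=1e-12, dense_output=True)
        # analytic: dV/dt = -(E*V - Vc/C)/R with V+Vc conserved
        lam = (E + 1.0 / C) / R
        v_inf = (sum(y0) / C) / (E + 1.0 / C)
        t = np.linspace(0, 1.0, 50)
        analytic = v_inf + (y0[0] - v_inf) * np.exp(-lam * t)
        assert sol.sol(t)[0] == pytest.approx(analytic, rel=1e-7)


class TestKernel:
    def test_python_and_compiled_paths_agree(self, npc_net):
        y0 = default_initial_state(npc_net)
        b_py = simulate_beat(npc_net, y0, backend="python")
        b_nb = simulate_beat(npc_net, y0, backend="numba")
        assert b_nb.y_end == pytest.approx(b_py.y_end, rel=1e-12, abs=1e-12)

    def test_fixed_step_matches_adaptive_lsoda(self, npc_net, baseline):
        """The RK4 kernel and an independent adaptive stiff integration of
        the same assembled ODEs give the same beat to ~0.1%."""
        y0 = baseline.state
        b_rk4 = simulate_beat(npc_net_calibrated(baseline), y0)
        b_sp = simulate_beat(npc_net_calibrated(baseline), y0, backend="scipy")
        co_rk4 = b_rk4.cardiac_output()
        co_sp = b_sp.mean_valve_flow("AV") * 0.06
        assert co_sp == pytest.approx(co_rk4, rel=2e-3)
        # final states agree everywhere volumes live
        lay = b_rk4.layout
        assert b_sp.y_end[lay.volume_states] == pytest.approx(
            b_rk4.y_end[lay.volume_states], rel=5e-3, abs=0.5
        )

    def test_total_volume_conserved_over_beats(self, npc_net):
        y = default_initial_state(npc_net)
        layout = StateLayout(len(npc_net.organs))
        v0 = np.sum(y[layout.volume_states])
        for _ in range(5):
            beat = simulate_beat(npc_net, y)
            y = beat.y_end
        assert np.sum(y[layout.volume_states]) == pytest.approx(v0, rel=1e-6)


def npc_net_calibrated(baseline):
    return baseline.net


class TestSteadyState:
    def test_steady_state_is_a_fixed_point(self, baseline):
        """One further beat from the converged state changes CO by <0.1%."""
        beat = simulate_beat(baseline.net, baseline.state)
        assert beat.cardiac_output() == pytest.approx(
            baseline.beat.cardiac_output(), rel=1e-3
        )

    def test_npc_cardiac_output_matches_target(self, baseline):
        assert baseline.report.metrics["CO_lmin"] == pytest.approx(4.9, rel=0.02)

    def test_volume_drift_below_tenth_percent(self, baseline):
        y = baseline.state.copy()
        layout = baseline.beat.layout
        v0 = np.sum(y[layout.volume_states])
        for _ in range(10):
            y = simulate_beat(baseline.net, y).y_end
        drift = abs(np.sum(y[layout.volume_states]) - v0) / v0
        assert drift < 1e-3

    def test_left_right_stroke_volume_balance(self, baseline):
        beat = baseline.beat
        sv_lv = beat.mean_valve_flow("AV") * beat.period
        sv_rv = beat.mean_valve_flow("PV") * beat.period
        assert sv_rv == pytest.approx(sv_lv, rel=0.01)

    def test_ventricular_pressure_ratio(self, baseline):
        beat = baseline.beat
        ratio = beat.chamber_pressure("LV").max() / beat.chamber_pressure("RV").max()
        assert 5.0 <= ratio <= 7.0

    def test_valve_rectification_and_semilunar_backflow(self, baseline):
        beat = baseline.beat
        for v in ("AV", "PV", "MV", "TV"):
            q = beat.valve_flow(v)
            fwd = np.trapezoid(np.clip(q, 0, None), beat.time)
            back = -np.trapezoid(np.clip(q, None, 0), beat.time)
            assert fwd > 20 * back
        # the small regurgitant spike at semilunar valve closure is present
        assert beat.valve_flow("AV").min() < -1.0

    def test_run_to_periodic_steady_state_driver(self, baseline):
        """The stand-alone steady-state driver reproduces the calibrated
        operating point when warm-started from it."""
        beat = hemo.run_to_periodic_steady_state(
            baseline.net, init=baseline.state, min_beats=30
        )
        assert beat.n_beat >= 30
        assert beat.cardiac_output() == pytest.approx(
            baseline.beat.cardiac_output(), rel=1e-3
        )

    def test_waveform_export_layout(self, baseline, tmp_path):
        """CSV export: one row per sample, `<element>.<signal>` columns."""
        df = baseline.beat.waveforms()
        assert "LV.p_mmHg" in df.columns
        assert "AV.q_ml_s" in df.columns
        assert "uterus.p_art_mmHg" in df.columns
        assert "LV.r_cm" in df.columns and "LV.h_cm" in df.columns
        path = tmp_path / "beat.csv"
        baseline.beat.to_csv(path)
        import pandas as pd

        back = pd.read_csv(path)
        assert list(back.columns) == list(df.columns)
        assert len(back) == len(baseline.beat.time)

    def test_atrial_thin_wall_condition(self, baseline):
        for c in ("LA", "RA"):
            r = baseline.beat.chamber_radius(c)
            h = baseline.beat.chamber_thickness(c)
            assert np.all(h / r < 0.1)
            assert np.all(h / r > 0)
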