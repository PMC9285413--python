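"""Stage parameter derivation, anthropometrics and myocardial split."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gravicor import config, parameterize
from gravicor.errors import ConfigError
from gravicor.hemo import CHAMBER_ORDER
from gravicor.parameterize import (
    build_stage_network,
    distribute_myocardium,
    organ_compartment_params,
    schlich_bsa,
    tricuspid_area_scale,
)


class TestOrganDerivation:
    def test_npc_uterus_reference_values(self):
        """Uterine bed at baseline: PerfP 76, CO 4.9 L/min, 0.44% of CO."""
        o = organ_compartment_params("uterus", 76.0, 4.9, 0.0044, 0.81)
        rtot = o.Rart + o.Rvb + o.Rven
        assert rtot == pytest.approx(211.5, rel=1e-3)
        assert o.Rvb == pytest.approx(194.6, rel=1e-3)
        assert o.Cart == pytest.approx(0.81 / 194.6, rel=1e-3)
        assert o.Cven == pytest.approx(30 * o.Cart, rel=1e-12)

    @given(st.floats(40, 110), st.floats(3, 8), st.floats(0.004, 0.4))
    def test_split_partitions_total(self, perfp, co, frac):
        o = organ_compartment_params("x", perfp, co, frac, 0.81)
        rtot = perfp / (frac * co * 1000 / 60)
        assert o.Rart + o.Rvb + o.Rven == pytest.approx(rtot, rel=1e-12)
        assert o.Rart == pytest.approx(0.05 * rtot, rel=1e-12)
        assert o.Rven == pytest.approx(0.03 * rtot, rel=1e-12)

    def test_doubling_fraction_halves_resistance(self):
        a = organ_compartment_params("x", 76, 4.9, 0.1, 0.81)
        b = organ_compartment_params("x", 76, 4.9, 0.2, 0.81)
        assert b.Rvb == pytest.approx(a.Rvb / 2, rel=1e-12)

    def test_zero_fraction_rejected(self):
        with pytest.raises(ConfigError):
            organ_compartment_params("x", 76, 4.9, 0.0, 0.81)


class TestSchlichBSA:
    def test_reference_woman(self):
        assert schlich_bsa(56, 167) == pytest.approx(1.56, abs=0.005)

    def test_direct_evaluation(self):
        assert schlich_bsa(65, 165) == pytest.approx(
            0.000975482 * 65**0.46 * 165**1.08, rel=1e-12
        )

    @given(st.floats(40, 120), st.floats(140, 200))
    def test_monotone_in_both_arguments(self, w, h):
        assert schlich_bsa(w + 1, h) > schlich_bsa(w, h)
        assert schlich_bsa(w, h + 1) > schlich_bsa(w, h)


class TestTricuspidRule:
    def test_symmetric_case(self):
        assert tricuspid_area_scale(1.10, 1.10, 1.10) == pytest.approx(1.10)

    def test_arithmetic(self):
        assert tricuspid_area_scale(1.12, 1.08, 1.10) == pytest.approx(1.0996, abs=1e-4)

    @given(st.floats(0.9, 1.3), st.floats(0.9, 1.3))
    def test_cancellation_when_mitral_tracks_aortic(self, s, pv):
        assert tricuspid_area_scale(s, pv, s) == pytest.approx(pv, rel=1e-12)


class TestMyocardialDistribution:
    def chambers(self, emax=(3.6, 0.5, 0.25, 0.16)):
        from gravicor.hemo import ChamberParams

        return [
            ChamberParams(name=n, Emax=e, Emin=e / 20, tau1=0.2, tau2=0.3,
                          m1=1.3, m2=20, vwall=10, shape="sphere")
            for n, e in zip(CHAMBER_ORDER, emax)
        ]

    def test_equal_weights_give_quarters(self):
        vw = distribute_myocardium(100.0, self.chambers((1, 1, 1, 1)))
        assert all(v == pytest.approx(25.0) for v in vw.values())

    def test_total_conserved(self):
        vw = distribute_myocardium(109.0, self.chambers())
        assert sum(vw.values()) == pytest.approx(109.0, abs=1e-9)

    def test_explicit_fractions_reference_lv_mass(self):
        vw = distribute_myocardium(
            109.0, self.chambers(), mode="explicit",
            fractions={"LV": 0.776, "RV": 0.145, "LA": 0.045, "RA": 0.034},
        )
        assert 1.04 * vw["LV"] == pytest.approx(88.0, abs=0.1)


class TestStageTable:
    def test_flow_fractions_sum_to_unity(self):
        stages = config.load_stages()
        for s in stages.values():
            assert sum(s.flow_fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_term_heart_rate_below_t3(self):
        # the stage table is used as published, including this non-monotone step
        stages = config.load_stages()
        assert stages["Term"].hr_bpm < stages["T3"].hr_bpm


class TestStageNetworks:
    def test_npc_stage_is_identity(self):
        stages = config.load_stages()
        npc_net = config.build_npc_network()
        rebuilt = build_stage_network(stages["NPC"], npc_net)
        for name in npc_net.organs:
            assert rebuilt.organs[name].Rvb == pytest.approx(
                npc_net.organs[name].Rvb, rel=1e-12
            )
        for v in npc_net.valves:
            assert rebuilt.valves[v].A_open == pytest.approx(
                npc_net.valves[v].A_open, rel=1e-12
            )

    def test_t3_uterine_fraction_in_resistance(self):
        stages = config.load_stages()
        net = build_stage_network(stages["T3"], config.build_npc_network())
        o = net.organs["uterus"]
        rtot = 76.0 / (0.1088 * 6.4 * 1000 / 60)
        assert o.Rart + o.Rvb + o.Rven == pytest.approx(rtot, rel=1e-9)

    def test_systemic_resistance_falls_from_npc_to_t1(self):
        stages = config.load_stages()
        npc = config.build_npc_network()
        t1 = build_stage_network(stages["T1"], npc)

        def rtot_parallel(net):
            g = sum(1.0 / (o.Rart + o.Rvb + o.Rven) for o in net.organs.values())
            return 1.0 / g

        assert rtot_parallel(t1) < rtot_parallel(npc)

    def test_idempotent(self):
        stages = config.load_stages()
        npc = config.build_npc_network()
        once = build_stage_network(stages["T2"], npc)
        twice = build_stage_network(stages["T2"], npc)
        assert config.network_to_dict(once) == config.network_to_dict(twice)

    def test_valve_scaling_applied_relative_to_npc(self):
        stages = config.load_stages()
        npc = config.build_npc_network()
        t3 = build_stage_network(stages["T3"], npc)
        assert t3.valves["AV"].A_open == pytest.approx(1.10 * npc.valves["AV"].A_open)
        assert t3.valves["TV"].A_open == pytest.approx(1.10 * npc.valves["TV"].A_open)


class TestConfigRoundTrip:
    def test_network_dict_round_trip(self):
        net = config.build_npc_network()
        d = config.network_to_dict(net)
        back = config.network_from_dict(d)
        assert config.network_to_dict(back) == d
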