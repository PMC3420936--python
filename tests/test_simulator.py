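"""Twin-domain kinetics: conservation, antisymmetry, fixed points, presets."""

from dataclasses import replace

import numpy as np
import pytest

from supercoil import (ChromosomeModel, SimState, TopoisomeraseParams,
                       TranscriptionUnit, build_model,
                       predicted_efficiency_profile, rif_experiment,
                       run_to_steady_state, step)

TOPOS_OFF = TopoisomeraseParams(k_gyrase=0.0, k_topo1=0.0, k_topo4=0.0)


def single_unit_model(n=12, v_e=52.5, activity=1.0, diffusion=0.0,
                      topo=TOPOS_OFF):
    unit = TranscriptionUnit(position=50.0, elongation_rate=v_e,
                             activity=activity)
    return ChromosomeModel(n_domains=n, units=(unit,), topo=topo,
                           diffusion_rate=diffusion)


class TestBuild:
    def test_wt_preset_dimensions(self):
        m = build_model("wt")
        assert m.n_domains == 450
        assert m.topo.k_gyrase == pytest.approx(4.5)
        assert len(m.units) == 45

    def test_gyrase_mutant_scalings(self):
        assert build_model("gyrA209").topo.k_gyrase == pytest.approx(2.25)
        assert build_model("gyrB1820").topo.k_gyrase == pytest.approx(0.45)
        assert build_model("parE206").topo.k_topo4 == pytest.approx(0.25)
        slow = build_model("rpoC")
        assert slow.units[0].elongation_rate == pytest.approx(52.5 * 0.6)

    def test_rif_zeroes_all_activities(self):
        m = build_model("gyrB1820", rif=True)
        assert all(u.activity == 0.0 for u in m.units)
        assert all(not u.is_barrier for u in m.units)

    def test_unknown_preset_lists_options(self):
        with pytest.raises(ValueError, match="wt"):
            build_model("gyrQ")

    def test_too_few_domains_rejected(self):
        with pytest.raises(ValueError, match="3 domains"):
            build_model({"preset": "wt", "n_domains": 2})

    def test_invalid_threshold_ordering(self):
        with pytest.raises(ValueError, match="below the gyrase"):
            TopoisomeraseParams(sigma_topo1_threshold=-0.02)


class TestStep:
    def test_quiescent_state_is_unchanged(self):
        m = ChromosomeModel(n_domains=10, units=(), topo=TOPOS_OFF,
                            diffusion_rate=0.0)
        s0 = SimState(sigma=np.full(10, -0.02))
        s1 = step(m, s0, 0.01)
        np.testing.assert_array_equal(s1.sigma, s0.sigma)

    def test_twin_domain_turns_after_ten_seconds(self):
        # one unit at 52.5 nt/s injects 5 sc/s: +-50 turns after 10 s
        m = single_unit_model()
        s = SimState(sigma=np.zeros(12))
        for _ in range(1000):
            s = step(m, s, 0.01)
        d = m.domain_of(50.0)
        lk0 = m.lk0_domain
        up, dn = (d - 1) % 12, (d + 1) % 12
        assert s.sigma[up] * lk0 == pytest.approx(-50.0, rel=1e-9)
        assert s.sigma[dn] * lk0 == pytest.approx(50.0, rel=1e-9)

    def test_linking_difference_conserved_without_topos(self):
        m = single_unit_model(diffusion=0.05)
        s = SimState(sigma=np.full(12, -0.038))
        start = s.linking_difference(m)
        for _ in range(500):
            s = step(m, s, 0.01)
        assert s.linking_difference(m) == pytest.approx(start, abs=1e-9)

    def test_twin_domain_antisymmetry(self):
        m = single_unit_model(diffusion=0.0)
        s = SimState(sigma=np.zeros(12))
        d = m.domain_of(50.0)
        for _ in range(777):
            s = step(m, s, 0.01)
            assert s.sigma[(d - 1) % 12] == -s.sigma[(d + 1) % 12]

    def test_instability_aborts(self):
        m = single_unit_model()
        s = SimState(sigma=np.zeros(12))
        with pytest.raises(RuntimeError, match="unstable"):
            for _ in range(100):
                s = step(m, s, 200.0)

    def test_nonpositive_dt_rejected(self):
        m = single_unit_model()
        with pytest.raises(ValueError):
            step(m, SimState(sigma=np.zeros(12)), 0.0)


class TestSteadyState:
    def test_no_units_relaxes_to_gyrase_setpoint(self):
        m = ChromosomeModel(n_domains=20, units=())
        s = run_to_steady_state(m, state=SimState(sigma=np.zeros(20)),
                                t_max=500.0)
        assert s.converged
        np.testing.assert_allclose(s.sigma, m.topo.sigma_setpoint, atol=1e-4)

    def test_single_unit_polarizes_neighbours(self):
        m = single_unit_model(n=30, topo=TopoisomeraseParams(),
                              diffusion=0.1, activity=0.9)
        s = run_to_steady_state(m, t_max=1000.0)
        d = m.domain_of(50.0)
        s_set = m.topo.sigma_setpoint
        assert s.sigma[(d - 1) % 30] < s_set < s.sigma[(d + 1) % 30]

    def test_flux_balance_matches_closed_form(self):
        # isolated downstream domain, influx phi = v_e/h <= k_gyrase:
        # steady sigma = sigma_set * (1 - phi / k_gyrase)
        m = build_model({"preset": "wt", "n_units": 1, "n_domains": 12,
                         "diffusion_rate": 0.0, "elongation_rate": 21.0,
                         "activity": 1.0, "k_topo4": 0.0})
        s = run_to_steady_state(m, t_max=150.0)
        phi = 21.0 / m.helical_repeat
        expected = m.topo.sigma_setpoint * (1 - phi / m.topo.k_gyrase)
        dn = (m.domain_of(m.units[0].position) + 1) % 12
        assert s.sigma[dn] == pytest.approx(expected, abs=1e-5)

    def test_rif_restores_setpoint_and_is_idempotent(self):
        m = build_model({"preset": "gyrB1820", "n_domains": 60,
                         "n_units": 6})
        s = run_to_steady_state(m, t_max=1500.0)
        reb = rif_experiment(m, s, t_max=1500.0)
        assert abs(reb.sigma.mean() - m.topo.sigma_setpoint) < 0.005
        again = rif_experiment(m, reb, t_max=500.0)
        np.testing.assert_allclose(again.sigma, reb.sigma, atol=1e-4)


class TestProfiles:
    def test_calibrated_positions(self, anchor_curve):
        m = ChromosomeModel(n_domains=10, units=())
        s = SimState(sigma=np.full(10, -0.030))
        eff = predicted_efficiency_profile(m, s, anchor_curve, [0.0, 55.0])
        np.testing.assert_allclose(eff, 0.50, atol=0.02)

    def test_relaxed_and_positive_domains_read_zero(self, curve):
        m = ChromosomeModel(n_domains=10, units=())
        s = SimState(sigma=np.array([0.0, 0.01] + [-0.03] * 8))
        eff = predicted_efficiency_profile(m, s, curve, [0.0, 10.0])
        assert eff[0] == 0.0 and eff[1] == 0.0

    def test_invalid_position_rejected(self, curve):
        m = ChromosomeModel(n_domains=10, units=())
        s = SimState(sigma=np.full(10, -0.03))
        with pytest.raises(ValueError):
            predicted_efficiency_profile(m, s, curve, [120.0])
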