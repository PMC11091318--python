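"""Two-compartment energy-budget model: fluxes, simulation, observables."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bsfdeb import (DebParams, LarvalState, Scenario, Stage,
                    partition_fluxes, predict_observables, prepupal_step,
                    simulate_deb, specific_assimilation, structural_demand)


class TestSpecificAssimilation:
    def test_logistic_midpoint(self):
        p = DebParams()
        assert specific_assimilation(p.x_A, p) == pytest.approx(p.a_max / 2)

    def test_near_max_at_hatching(self):
        p = DebParams(k_A=15.0, x_A=0.85)
        assert specific_assimilation(0.0, p) == pytest.approx(p.a_max,
                                                              rel=1e-5)
        # and with package defaults it stays >= 99% of a_max
        d = DebParams()
        assert specific_assimilation(0.0, d) >= 0.99 * d.a_max
        assert specific_assimilation(1.0, d) <= 0.15 * d.a_max

    def test_monotone_decline(self):
        p = DebParams()
        assert specific_assimilation(0.2, p) > specific_assimilation(0.8, p)

    def test_domain(self):
        with pytest.raises(ValueError):
            specific_assimilation(1.2, DebParams())


class TestStructuralDemand:
    def test_midpoint(self):
        p = DebParams()
        assert structural_demand(p.x5, 10.0, p) == pytest.approx(
            p.s_max * 10.0 / 2)

    def test_early_tail_near_smax(self):
        p = DebParams(k_B=10.0, x5=0.5)
        assert structural_demand(0.05, 1.0, p) == pytest.approx(
            p.s_max, rel=0.02)

    def test_late_tail_vanishes(self):
        p = DebParams()
        assert structural_demand(0.95, 1.0, p) < 0.02 * p.s_max


class TestPartitionFluxes:
    SC = Scenario(Xmax=30.0, X0=0.06)

    def _state(self, B, L=0.0):
        return LarvalState(t=0.0, B=B, L=L)

    def test_supply_limited_branch(self):
        # a(x) ~ a_max/2 with k_A ~ 0: r_A = 1.0 at X = 10
        p = DebParams(a_max=0.2, k_A=1e-6, m=0.08, Y=0.44, s_max=50.0,
                      x5=1.0, k_B=1e-6)
        f = partition_fluxes(self._state(10.0), p, self.SC)
        assert f.r_A == pytest.approx(1.0, rel=1e-5)
        assert f.r_CO2_m == pytest.approx(0.8)
        assert f.r_B == pytest.approx(0.2 / 1.44, rel=1e-4)
        assert f.r_CO2_B == pytest.approx(0.44 * 0.2 / 1.44, rel=1e-4)
        assert f.r_L == pytest.approx(0.0, abs=1e-9)

    def test_demand_limited_branch(self):
        # same supply, structural demand capped at 0.05 mg C/day
        # (logistic factor ~ 1/2 at k_B ~ 0, so s_max B / 2 = 0.05)
        p = DebParams(a_max=0.2, k_A=1e-6, m=0.08, Y=0.44, Y_L=0.38,
                      s_max=0.01, x5=1.0, k_B=1e-6)
        f = partition_fluxes(self._state(10.0), p, self.SC)
        assert f.r_B == pytest.approx(0.05, rel=1e-4)
        assert f.r_CO2_B == pytest.approx(0.022, rel=1e-4)
        assert f.r_L == pytest.approx(0.128 / 1.38, rel=1e-4)
        assert f.r_CO2_L == pytest.approx(0.38 * 0.128 / 1.38, rel=1e-4)

    def test_maintenance_only_point(self):
        # supply exactly covers maintenance: no growth, exact closure
        p = DebParams(a_max=0.16, k_A=1e-9, m=0.08, s_max=1.0)
        f = partition_fluxes(self._state(10.0), p, self.SC)
        assert f.r_B == pytest.approx(0.0, abs=1e-9)
        assert f.r_L == pytest.approx(0.0, abs=1e-9)
        assert f.r_A == pytest.approx(f.r_CO2_m, rel=1e-9)

    def test_starvation_draws_lipid(self):
        p = DebParams(a_max=0.05, k_A=1e-6, m=0.08)
        f = partition_fluxes(self._state(8.0, L=2.0), p, self.SC)
        assert f.starving
        assert f.r_B == 0.0
        assert f.r_L < 0
        assert f.r_CO2_L == 0.0
        assert f.r_CO2_m == pytest.approx(0.08 * 10.0)

    @settings(max_examples=100, deadline=None)
    @given(B=st.floats(0.1, 30.0), Lfrac=st.floats(0.0, 0.8),
           a_max=st.floats(0.3, 2.5), Y=st.floats(0.05, 1.0),
           m=st.floats(0.0, 0.3), s_max=st.floats(0.2, 2.0))
    def test_carbon_closure_exact(self, B, Lfrac, a_max, Y, m, s_max):
        p = DebParams(a_max=a_max, Y=Y, m=m, s_max=s_max)
        L = B * Lfrac / (1 - Lfrac + 1e-9)
        sc = Scenario(Xmax=max(1.06 * (B + L), 30.0), X0=0.06)
        f = partition_fluxes(LarvalState(t=0, B=B, L=L), p, sc)
        lhs = f.r_A
        rhs = f.r_B + f.r_L + f.r_CO2_B + f.r_CO2_L + f.r_CO2_m
        assert rhs == pytest.approx(lhs, rel=1e-9, abs=1e-12)
        assert f.r_CO2_B >= 0 and f.r_CO2_L >= 0 and f.r_CO2_m >= 0


class TestPrepupalStep:
    def test_maintenance_from_lipid(self):
        st_ = LarvalState(t=12.0, B=40.0, L=20.0, stage=Stage.PREPUPA)
        f = prepupal_step(st_, DebParams(m=0.08))
        assert f.r_A == 0.0 and f.r_B == 0.0
        assert f.r_L == pytest.approx(-4.8)
        assert f.r_CO2_m == pytest.approx(4.8)

    def test_weight_strictly_decreasing(self, chicken_params):
        sc = Scenario(t_end=18.0)
        traj = simulate_deb(chicken_params, sc)
        after = traj.t > traj.t_pp
        assert np.all(np.diff(traj.X[after]) < 0)

    def test_lipid_depletion_terminates(self, chicken_params):
        sc = Scenario(t_end=60.0)
        traj = simulate_deb(chicken_params, sc)
        assert traj.lipid_depleted
        assert traj.t[-1] < 60.0
        assert traj.L[-1] == pytest.approx(0.0, abs=1e-6)


class TestSimulate:
    def test_cumulative_conservation(self, chicken_traj):
        tr = chicken_traj
        gap = tr.A_cum[-1] - (tr.B[-1] - tr.B[0]) - (tr.L[-1] - tr.L[0]) \
            - tr.CO2_cum[-1]
        assert abs(gap) / tr.A_cum[-1] <= 1e-6

    def test_sigmoid_single_inflection(self, chicken_traj):
        mask = chicken_traj.t <= chicken_traj.t_pp
        X = chicken_traj.X[mask]
        assert np.all(np.diff(X) > 0)
        d2 = np.diff(X, 2)
        d2 = d2[np.abs(d2) > 1e-10]
        assert np.sum(np.diff(np.sign(d2)) != 0) == 1

    def test_xmax_scaling_invariance(self, chicken_params):
        ts, nges = [], []
        from bsfdeb import nge_average
        for s in (0.5, 1.0, 4.0):
            sc = Scenario(Xmax=30 * s, X0=0.06 * s)
            tr = simulate_deb(chicken_params, sc)
            ts.append(tr.t_pp)
            nges.append(nge_average(tr).nge_avg)
        assert np.ptp(ts) < 1e-3
        assert np.ptp(nges) < 1e-5

    def test_time_grid_and_cumulatives_monotone(self, chicken_traj):
        assert np.all(np.diff(chicken_traj.t) > 0)
        assert np.all(np.diff(chicken_traj.A_cum) >= 0)

    def test_prepupation_time_recorded(self, chicken_traj):
        assert np.isfinite(chicken_traj.t_pp)
        assert 8.0 < chicken_traj.t_pp < 16.0


class TestPredictObservables:
    def test_lean_larva_contents(self, chicken_params):
        sc = Scenario(t_end=2.0, harvest_rule="fixed-time")
        tr = simulate_deb(chicken_params, sc)
        obs = predict_observables(tr)
        early = obs["t"] <= 1.0  # lipid-free start
        assert np.allclose(obs["delta_lipid"][early], 0.0, atol=1e-9)
        assert np.allclose(obs["delta_DW"][early],
                           1.0 / (1 + chicken_params.h), atol=1e-9)

    def test_delta_dw_increases_with_lipid(self):
        # at fixed structure, fattier larvae have higher dry-matter content
        p = DebParams()
        B = 10.0
        prev = 0.0
        for L in (0.0, 5.0, 50.0, 5000.0):
            x_dw = (B + L) / p.f_C
            d = x_dw / (x_dw + p.h * B / p.f_C)
            assert d > prev
            prev = d
        assert prev > 0.99  # -> 1 in the anhydrous-lipid limit

    def test_lipid_content_nondecreasing_in_larval_phase(self, chicken_traj):
        obs = predict_observables(chicken_traj)
        mask = chicken_traj.t <= chicken_traj.t_pp
        dl = obs["delta_lipid"][mask]
        assert np.all(np.diff(dl) >= -1e-9)

    def test_co2_unit_conversion(self, chicken_traj):
        obs = predict_observables(chicken_traj)
        r_c = np.array([f.r_CO2 for f in chicken_traj.fluxes])
        assert np.allclose(obs["r_CO2"], r_c * 44.0 / 12.0)
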