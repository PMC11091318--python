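"""NGE computation and mass-balance performance indicators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bsfdeb import (Indicators, MassBalanceLedger, complete_indicators,
                    indicators_from_ledger, nge_average, nge_instantaneous,
                    table_summary)
from bsfdeb.efficiency import (CannotCompleteError, UndefinedRatioError,
                               load_reference_indicators)


class TestNgeInstantaneous:
    @pytest.mark.parametrize("r_X, r_A, expected",
                             [(1.0, 1.0, 1.0), (0.5, 1.0, 0.5)])
    def test_ratio(self, r_X, r_A, expected):
        assert nge_instantaneous(r_X, r_A) == expected

    def test_zero_assimilation_raises(self):
        with pytest.raises(UndefinedRatioError):
            nge_instantaneous(0.2317, 0.0)


class TestNgeAverage:
    def test_matches_trapezoid_oracle(self, chicken_traj):
        # independent route: trapezoid integrals of the flux series
        tr = chicken_traj
        mask = tr.t <= tr.t_pp
        r_X = np.array([f.r_X for f in tr.fluxes])[mask]
        r_A = np.array([f.r_A for f in tr.fluxes])[mask]
        t = tr.t[mask]
        oracle = np.trapezoid(r_X, t) / np.trapezoid(r_A, t)
        res = nge_average(tr, tr.scenario.t0, tr.t_pp)
        assert res.nge_avg == pytest.approx(oracle, rel=1e-4)

    def test_late_harvest_lowers_efficiency(self, chicken_traj):
        at_pp = nge_average(chicken_traj, t_harvest=chicken_traj.t_pp)
        late = nge_average(chicken_traj,
                           t_harvest=min(chicken_traj.t_pp + 5,
                                         chicken_traj.t[-1]))
        assert late.nge_avg < at_pp.nge_avg

    def test_series_has_nan_when_feeding_stops(self, chicken_traj):
        res = nge_average(chicken_traj)
        after = chicken_traj.t > chicken_traj.t_pp
        assert np.all(np.isnan(res.nge_series[after]))
        before = chicken_traj.t < chicken_traj.t_pp
        assert np.all(~np.isnan(res.nge_series[before]))


class TestIndicatorsFromLedger:
    def test_literature_style_ledger(self):
        led = MassBalanceLedger(X_DW0=0, X_DW=18, W_DW0=100, W_DW_res=56)
        ind = indicators_from_ledger(led)
        assert ind.BR == pytest.approx(0.18)
        assert ind.SRR == pytest.approx(0.44)
        assert round(ind.SCE, 2) == 0.41
        assert round(ind.SCR, 1) == 2.4

    def test_no_growth(self):
        led = MassBalanceLedger(X_DW0=5, X_DW=5, W_DW0=100, W_DW_res=60)
        ind = indicators_from_ledger(led)
        assert ind.BR == 0.0 and ind.SCE == 0.0
        assert ind.SCR is None
        assert ind.provenance["SCR"] == "undefined"

    def test_all_substrate_consumed(self):
        led = MassBalanceLedger(X_DW0=0, X_DW=30, W_DW0=100, W_DW_res=0)
        ind = indicators_from_ledger(led)
        assert ind.SRR == pytest.approx(1.0)
        assert ind.SCE == pytest.approx(ind.BR)

    @settings(max_examples=100, deadline=None)
    @given(x0=st.floats(0, 10), gain=st.floats(0.01, 50),
           w0=st.floats(10, 1000), removed_frac=st.floats(0.05, 1.0))
    def test_br_equals_sce_times_srr(self, x0, gain, w0, removed_frac):
        led = MassBalanceLedger(X_DW0=x0, X_DW=x0 + gain, W_DW0=w0,
                                W_DW_res=w0 * (1 - removed_frac))
        ind = indicators_from_ledger(led)
        assert ind.BR == pytest.approx(ind.SCE * ind.SRR, rel=1e-12)
        assert ind.SCR == pytest.approx(1.0 / ind.SCE, rel=1e-12)


class TestCompleteIndicators:
    def test_from_scr(self):
        out = complete_indicators(Indicators(SCR=3.75))
        assert round(out.SCE, 2) == 0.27
        assert out.provenance["SCE"] == "derived-from-identity"

    def test_from_br_and_srr(self):
        out = complete_indicators(Indicators(BR=0.13, SRR=0.85))
        assert round(out.SCE, 2) == 0.15

    def test_idempotent(self):
        once = complete_indicators(Indicators(SCE=0.5))
        assert once.SCR == pytest.approx(2.0)
        twice = complete_indicators(once)
        for k in ("BR", "SCE", "SCR", "SRR"):
            assert getattr(twice, k) == getattr(once, k)

    def test_consistency_with_ledger_route(self):
        led = MassBalanceLedger(X_DW0=0, X_DW=18, W_DW0=100, W_DW_res=56)
        direct = indicators_from_ledger(led)
        derived = complete_indicators(
            Indicators(BR=direct.BR, SRR=direct.SRR))
        assert derived.SCE == pytest.approx(direct.SCE, rel=1e-12)

    def test_inconsistent_routes_flagged(self):
        out = complete_indicators(Indicators(SCE=0.5, SCR=2.5))
        assert out.inconsistent

    def test_insufficient_fields(self):
        with pytest.raises(CannotCompleteError):
            complete_indicators(Indicators(BR=0.2))


class TestReferenceTable:
    def test_packaged_rows_range(self):
        rows = load_reference_indicators()
        assert len(rows) == 12
        summ = table_summary(rows)
        assert summ["SCE"]["min"] == pytest.approx(0.14)
        assert summ["SCE"]["max"] == pytest.approx(0.48)
        assert summ["SCE"]["n"] == 12

    def test_single_row(self):
        summ = table_summary([Indicators(SCE=0.3)])
        assert summ["SCE"]["min"] == summ["SCE"]["max"] == 0.3

    def test_absent_indicator_marked(self):
        summ = table_summary([Indicators(SCE=0.3), Indicators(SCE=0.2)])
        assert summ["SCR"]["n"] == 0 and summ["SCR"]["min"] is None

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            table_summary([])
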