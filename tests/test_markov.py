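import math

import numpy as np
import pytest

from kirblock import (
    SolutionCondition,
    StateModel,
    apparent_kd,
    build_generator,
    initial_block_rate,
    rate_off,
    rate_on,
    relax_occupancy,
    steady_state,
)
from kirblock.errors import ConfigurationError
from kirblock.params import BlockerSpec, override

from oracles import bisect_root, euler_occupancy, gillespie_mean_occupancy


def cond_with(conc, blocker="X", k=100.0):
    return SolutionCondition(k, k, {blocker: conc})


class TestRates:
    def test_zero_concentration_gives_zero_on_rate(self, simple_blocker):
        assert rate_on(simple_blocker, 50.0, cond_with(0.0)) == 0.0

    def test_on_rate_at_zero_mv_is_kon_times_conc(self):
        b = BlockerSpec(id="X", valence=2, kon0=1.2e6, delta_on=0.075,
                        koff0=100.0, zdelta_off=0.5)
        assert rate_on(b, 0.0, cond_with(1e-6)) == pytest.approx(1.2)

    def test_on_rate_exponential_voltage_dependence(self):
        # kon0=1.2e6 M^-1 s^-1, Z*delta=0.15 per 25 mV, [B]=100 uM, V=+100
        b = BlockerSpec(id="X", valence=2, kon0=1.2e6, delta_on=0.075,
                        koff0=100.0, zdelta_off=0.5)
        expected = 1.2e6 * 1e-4 * math.exp(0.6)
        assert rate_on(b, 100.0, cond_with(1e-4)) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(218.7, rel=1e-3)

    def test_off_rate_at_zero_mv_symmetric_is_koff0(self, simple_blocker):
        assert rate_off(simple_blocker, 0.0, cond_with(1e-4)) == pytest.approx(100.0)

    def test_off_rate_woodhull_at_negative_voltage(self):
        # published pair koff0=280 s^-1, Zdelta=0.67: at -100 mV, 280*e^2.68
        b = BlockerSpec(id="X", valence=2, kon0=1.2e6, delta_on=0.075,
                        koff0=280.0, zdelta_off=0.67)
        r = rate_off(b, -100.0, cond_with(1e-4))
        assert r == pytest.approx(280.0 * math.exp(2.68), rel=1e-12)
        assert r == pytest.approx(4085.0, rel=1e-3)

    def test_flux_coupling_vanishes_at_reversal_potential(self):
        b = BlockerSpec(id="X", valence=2, kon0=1.2e6, delta_on=0.075,
                        koff0=280.0, zdelta_off=0.67, theta=3.0, vs=15.0)
        b0 = override(b, theta=0.0)
        cond = SolutionCondition(100.0, 20.0, {"X": 1e-4})  # EK ~ -40 mV
        assert rate_off(b, cond.ek, cond) == pytest.approx(
            rate_off(b0, cond.ek, cond), rel=1e-12
        )

    def test_flux_coupling_retards_unblocking_for_outward_flux(self):
        b = BlockerSpec(id="X", valence=2, kon0=1.2e6, delta_on=0.075,
                        koff0=280.0, zdelta_off=0.67, theta=3.0, vs=15.0)
        b0 = override(b, theta=0.0)
        c = cond_with(1e-4)
        assert rate_off(b, 60.0, c) < rate_off(b0, 60.0, c)
        # inward flux: purely Woodhull
        assert rate_off(b, -60.0, c) == pytest.approx(rate_off(b0, -60.0, c))

    def test_missing_blocker_concentration(self, simple_blocker):
        with pytest.raises(ConfigurationError):
            rate_on(simple_blocker, 0.0, SolutionCondition(100, 100, {"Mg": 0.0}))


class TestGenerator:
    def test_rows_sum_to_zero_and_offdiag_nonneg(self, mg_wt, spm_wt, sym100):
        model = StateModel([mg_wt, spm_wt])
        cond = sym100.with_blocker("Mg", 1e-3).with_blocker("SPM", 1e-5)
        for v in (-120.0, -40.0, 0.0, 40.0, 120.0):
            Q = build_generator(model, v, cond)
            assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12 * max(1, Q.max()))
            off_diag = Q[~np.eye(4, dtype=bool)]
            assert np.all(off_diag >= 0)

    def test_two_state_eigenvalues(self, simple_model, simple_blocker):
        cond = cond_with(1e-4)
        Q = build_generator(simple_model, 40.0, cond)
        lam = np.sort(np.linalg.eigvals(Q).real)
        total = rate_on(simple_blocker, 40.0, cond) + rate_off(
            simple_blocker, 40.0, cond
        )
        assert lam[1] == pytest.approx(0.0, abs=1e-9)
        assert lam[0] == pytest.approx(-total, rel=1e-12)

    def test_zero_concentration_absorbing_open_state(self, simple_model):
        Q = build_generator(simple_model, 0.0, cond_with(0.0))
        assert Q[0, 1] == 0.0
        assert Q[1, 0] > 0

    def test_punch_through_blocked_from_doubly_occupied_state(self, mg_wt, spm_wt):
        cond = SolutionCondition(100, 100, {"Mg": 1e-3, "SPM": 1e-5})
        occl = build_generator(StateModel([mg_wt, spm_wt]), 100.0, cond)
        free = build_generator(
            StateModel([mg_wt, spm_wt], ms_blocks_exit=False), 100.0, cond
        )
        O, M, S, MS = 0, 1, 2, 3
        # S->O includes punch-through in both; MS->M only when exit is free
        assert occl[S, O] == free[S, O]
        assert occl[MS, M] < free[MS, M]

    def test_inconsistent_condition_raises(self, simple_model):
        with pytest.raises(ConfigurationError):
            build_generator(simple_model, 0.0, SolutionCondition(100, 100, {}))


class TestSteadyState:
    def test_no_blocker_fully_open(self, simple_model):
        p = steady_state(simple_model, 0.0, cond_with(0.0))
        assert p == pytest.approx([1.0, 0.0], abs=1e-12)

    def test_half_block_at_apparent_kd(self, simple_model, simple_blocker):
        v = 30.0
        kd = apparent_kd(simple_model, v, cond_with(0.0))
        p = steady_state(simple_model, v, cond_with(kd))
        assert p[0] == pytest.approx(0.5, rel=1e-10)

    def test_boltzmann_ratio_without_flux_coupling(self, simple_blocker):
        # detailed-balance special case: P_O = koff/(kon[B]+koff) exactly
        model = StateModel([simple_blocker])
        cond = cond_with(2e-4)
        v = -20.0
        a = rate_on(simple_blocker, v, cond)
        k = rate_off(simple_blocker, v, cond)
        p = steady_state(model, v, cond)
        assert p[0] == pytest.approx(k / (a + k), rel=1e-12)

    def test_punch_through_steady_state_vs_hand_solved_balance(self):
        # O <-> S with S->O punch-through: P_O = (koff+kexit)/(kon[B]+koff+kexit)
        b = BlockerSpec(id="S", valence=4, kon0=1e7, delta_on=0.06, koff0=30.0,
                        zdelta_off=1.0, kexit0=0.5, zdelta_exit=1.0)
        model = StateModel([b])
        cond = SolutionCondition(100, 100, {"S": 2e-6})
        v = 60.0
        a = rate_on(b, v, cond)
        k = rate_off(b, v, cond)
        e = b.kexit0 * math.exp(b.zdelta_exit * v / 25.0)
        p = steady_state(model, v, cond)
        assert p[0] == pytest.approx((k + e) / (a + k + e), rel=1e-9)

    def test_four_state_steady_state_vs_hand_solved_balance(self, mg_wt, spm_wt):
        # independent-site scheme (exit allowed from MS): occupancies factorize
        cond = SolutionCondition(100, 100, {"Mg": 1e-4, "SPM": 1e-7})
        v = 40.0
        model = StateModel([mg_wt, spm_wt], ms_blocks_exit=False)
        p = steady_state(model, v, cond)
        am, km = rate_on(mg_wt, v, cond), rate_off(mg_wt, v, cond)
        aspm = rate_on(spm_wt, v, cond)
        kspm = rate_off(spm_wt, v, cond) + spm_wt.kexit0 * math.exp(
            spm_wt.zdelta_exit * v / 25.0
        )
        xm, xs = am / km, aspm / kspm
        expected_po = 1.0 / ((1 + xm) * (1 + xs))
        assert p[0] == pytest.approx(expected_po, rel=1e-9)

    def test_reducible_chain_raises(self, simple_model, monkeypatch):
        # a generator with no transitions at all has no unique stationary state
        import kirblock.markov as mk

        monkeypatch.setattr(
            mk, "build_generator", lambda model, v, cond: np.zeros((2, 2))
        )
        with pytest.raises(ConfigurationError, match="reducible|not unique"):
            mk.steady_state(simple_model, 0.0, cond_with(0.0))


class TestApparentKd:
    def test_zero_mv_is_koff_over_kon(self, simple_model, simple_blocker):
        kd = apparent_kd(simple_model, 0.0, cond_with(0.0))
        assert kd == pytest.approx(simple_blocker.koff0 / simple_blocker.kon0)

    def test_punch_through_raises_kd(self, spm_wt, sym100):
        base = StateModel([override(spm_wt, kexit0=0.0)])
        punch = StateModel([spm_wt])
        v = 80.0
        assert apparent_kd(punch, v, sym100) > apparent_kd(base, v, sym100)

    def test_matches_bisection_on_steady_state(self, mg_wt, sym100):
        model = StateModel([mg_wt])
        for v in (-40.0, 10.0, 60.0):
            kd = apparent_kd(model, v, sym100)

            def half_block(conc, v=v):
                return steady_state(model, v, sym100.with_blocker("Mg", conc))[0] - 0.5

            root = bisect_root(half_block, kd * 1e-3, kd * 1e3, tol=1e-12)
            assert root == pytest.approx(kd, rel=1e-9)

    def test_kd_monotone_decreasing_above_reversal(self, mg_wt, sym100):
        model = StateModel([mg_wt])
        kds = [apparent_kd(model, v, sym100) for v in np.arange(0.0, 101.0, 5.0)]
        assert np.all(np.diff(kds) < 0)

    def test_two_blocker_model_unsupported(self, mg_wt, spm_wt, sym100):
        with pytest.raises(ConfigurationError):
            apparent_kd(StateModel([mg_wt, spm_wt]), 0.0, sym100)


class TestRelaxation:
    def test_two_state_closed_form(self, simple_model, simple_blocker):
        cond = cond_with(1e-4)
        v = 50.0
        a = rate_on(simple_blocker, v, cond)
        k = rate_off(simple_blocker, v, cond)
        p_inf = k / (a + k)
        t = np.linspace(0.0, 0.05, 200)
        occ = relax_occupancy(simple_model, v, cond, [1.0, 0.0], t)
        expected = p_inf + (1 - p_inf) * np.exp(-(a + k) * t)
        assert np.allclose(occ[:, 0], expected, rtol=1e-9, atol=1e-12)

    def test_t0_returns_p0_and_conserves_probability(self, mg_wt, spm_wt):
        cond = SolutionCondition(100, 100, {"Mg": 1e-4, "SPM": 1e-7})
        model = StateModel([mg_wt, spm_wt])
        p0 = np.array([0.4, 0.3, 0.2, 0.1])
        t = np.linspace(0, 0.2, 101)
        occ = relax_occupancy(model, 60.0, cond, p0, t)
        assert occ[0] == pytest.approx(p0, abs=1e-10)
        assert np.allclose(occ.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(occ >= 0)

    def test_long_time_limit_is_steady_state(self, mg_wt, spm_wt):
        cond = SolutionCondition(100, 100, {"Mg": 1e-4, "SPM": 1e-7})
        model = StateModel([mg_wt, spm_wt])
        # at 0 mV every relaxation mode is faster than ~30 s^-1
        occ = relax_occupancy(model, 0.0, cond, [1, 0, 0, 0], [10.0])
        ss = steady_state(model, 0.0, cond)
        assert occ[0] == pytest.approx(ss, abs=1e-9)

    def test_unnormalized_p0_rejected(self, simple_model):
        with pytest.raises(ValueError):
            relax_occupancy(simple_model, 0.0, cond_with(1e-4), [0.7, 0.6], [0.01])

    def test_matches_microstep_integration(self, mg_wt, spm_wt):
        # moderate rates so explicit Euler at 1 us is stable and accurate
        cond = SolutionCondition(100, 100, {"Mg": 5e-5, "SPM": 2e-8})
        model = StateModel([mg_wt, spm_wt])
        v = 50.0
        from kirblock.markov import build_generator

        Q = build_generator(model, v, cond)
        t_end = 0.02
        p_euler = euler_occupancy(Q, np.array([1.0, 0, 0, 0]), t_end, dt=1e-6)
        p_eig = relax_occupancy(model, v, cond, [1, 0, 0, 0], [t_end])[0]
        assert np.allclose(p_eig, p_euler, atol=1e-6)

    def test_matches_gillespie_ensemble(self, simple_model, simple_blocker, rng):
        cond = cond_with(1e-4)
        v = 30.0
        from kirblock.markov import build_generator

        Q = build_generator(simple_model, v, cond)
        t_grid = np.array([0.002, 0.005, 0.01, 0.02])
        n = 100_000
        mc = gillespie_mean_occupancy(Q, np.array([1.0, 0.0]), t_grid, n, rng)
        occ = relax_occupancy(simple_model, v, cond, [1.0, 0.0], t_grid)
        se = np.sqrt(np.clip(occ[:, 0] * (1 - occ[:, 0]), 1e-12, None) / n)
        assert np.all(np.abs(mc[:, 0] - occ[:, 0]) <= 3 * se + 1e-9)


def test_initial_block_rate_additive_over_blockers(mg_wt, spm_wt):
    cond = SolutionCondition(100, 100, {"Mg": 1e-5, "SPM": 1e-8})
    v = 100.0
    both = initial_block_rate(StateModel([mg_wt, spm_wt]), v, cond)
    only_mg = initial_block_rate(StateModel([mg_wt]), v, cond)
    only_spm = initial_block_rate(StateModel([spm_wt]), v, cond)
    assert both == pytest.approx(only_mg + only_spm, rel=1e-12)
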