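import numpy as np
import pytest

from kirblock import (
    SolutionCondition,
    StateModel,
    apparent_kd,
    coupling_coefficient,
    cycle_scan,
    generate_experiment,
    initial_block_rate,
    relax_occupancy,
    synergy_kinetics,
    synergy_steady_state,
)
from kirblock.designs import synergy_design
from kirblock.errors import DesignError
from kirblock.params import blocker_preset, load_presets


class TestCouplingCoefficient:
    def test_multiplicative_double_gives_unity(self):
        kd_wt, kd_a, kd_b = 1e-4, 3e-4, 5e-4
        kd_ab = kd_a * kd_b / kd_wt
        res = coupling_coefficient(kd_wt, kd_a, kd_b, kd_ab)
        assert res.omega == pytest.approx(1.0, rel=1e-12)
        assert res.verdict == "additive"

    def test_direct_arithmetic_example(self):
        # (3 * 5) / 30 = 0.5 in units of the WT Kd
        res = coupling_coefficient(100e-6, 300e-6, 500e-6, 3000e-6)
        assert res.omega == pytest.approx(0.5, rel=1e-12)

    def test_symmetric_in_mutant_order(self):
        a = coupling_coefficient(1e-4, 2e-4, 9e-4, 5e-3)
        b = coupling_coefficient(1e-4, 9e-4, 2e-4, 5e-3)
        assert a.omega == pytest.approx(b.omega, rel=1e-12)

    def test_invariant_to_kd_units(self):
        omega_m = coupling_coefficient(1e-4, 2e-4, 9e-4, 5e-3).omega
        omega_um = coupling_coefficient(100.0, 200.0, 900.0, 5000.0).omega
        assert omega_m == pytest.approx(omega_um, rel=1e-12)

    def test_nonpositive_kd_rejected(self):
        with pytest.raises(ValueError):
            coupling_coefficient(0.0, 1e-4, 1e-4, 1e-4)


@pytest.fixture(scope="module")
def kd_table_40mv():
    """Closed-form apparent Kd at +40 mV per preset genotype."""
    cond = SolutionCondition(100.0, 100.0, {"Mg": 0.0})
    table = {}
    for geno in load_presets()["genotypes"]:
        model = StateModel([blocker_preset("Mg", geno)])
        table[geno] = apparent_kd(model, 40.0, cond)
    return table


class TestCycleScan:
    def test_additively_built_doubles_have_unit_omega(self, kd_table_40mv):
        results, _ = cycle_scan(
            kd_table_40mv, [("E224G", "D172N"), ("E224G", "A184Q")], v=40.0
        )
        for r in results:
            assert r.omega == pytest.approx(1.0, rel=1e-6)
            assert r.verdict == "additive"

    def test_bundle_crossing_doubles_negative_cooperative(self, kd_table_40mv):
        results, _ = cycle_scan(
            kd_table_40mv, [("E224G", "G177N"), ("E224G", "M183N")], v=40.0
        )
        for r in results:
            assert r.omega < 0.5
            assert r.verdict == "negative-cooperative"
        # calibrated to the magnitude of the published coupling coefficients
        omegas = sorted(r.omega for r in results)
        assert omegas[0] == pytest.approx(0.08, rel=0.05)
        assert omegas[1] == pytest.approx(0.14, rel=0.05)

    def test_missing_genotype_listed_as_skipped(self, kd_table_40mv):
        results, skipped = cycle_scan(kd_table_40mv, [("E224G", "Q999X")], v=40.0)
        assert not results
        assert skipped and "Q999X" in skipped[0][1]

    def test_results_sorted_by_omega(self, kd_table_40mv):
        results, _ = cycle_scan(
            kd_table_40mv,
            [("E224G", "D172N"), ("E224G", "G177N"), ("E224G", "M183N")],
            v=40.0,
        )
        omegas = [r.omega for r in results]
        assert omegas == sorted(omegas)


@pytest.fixture(scope="module")
def low_conc_synergy_experiment():
    """Low-concentration two-blocker design (0.1 uM Mg, 0.01 uM SPM)."""
    cells = synergy_design(voltages=(100.0,), noise_sd=0.0, test_ms=300.0)
    return generate_experiment(cells, seed=0)


class TestSteadyStateSynergy:
    def test_full_model_flags_synergy_at_plus100(self, low_conc_synergy_experiment):
        res = synergy_steady_state(low_conc_synergy_experiment, 100.0)
        assert res.f_both < res.f_pred_independent
        assert res.f_both < res.f_pred_competition
        assert res.flags["steady_state_synergy"]

    def test_independent_site_model_matches_product_null(self):
        # punch-through allowed from the doubly occupied state: no interaction
        cells = synergy_design(
            voltages=(100.0,), noise_sd=0.0, test_ms=300.0, ms_blocks_exit=False
        )
        exp = generate_experiment(cells, seed=0)
        res = synergy_steady_state(exp, 100.0)
        assert res.f_both == pytest.approx(res.f_pred_independent, rel=5e-3)
        assert not res.flags["steady_state_synergy"]

    def test_blocker_a_absent_reduces_to_single_blocker(self):
        cells = synergy_design(mg_conc=0.0, voltages=(100.0,), noise_sd=0.0)
        exp = generate_experiment(cells, seed=0)
        res = synergy_steady_state(exp, 100.0)
        assert res.f_a == pytest.approx(1.0, rel=1e-9)
        assert res.f_pred_independent == pytest.approx(res.f_b, rel=1e-9)

    def test_missing_group_raises(self, low_conc_synergy_experiment):
        crippled = type(low_conc_synergy_experiment)(
            sweeps=[
                sw for sw in low_conc_synergy_experiment.sweeps if sw.meta["group"] != "AB"
            ],
            design=low_conc_synergy_experiment.design,
        )
        with pytest.raises(DesignError):
            synergy_steady_state(crippled, 100.0)


class TestKineticAdditivity:
    def test_binding_rates_roughly_additive_in_study_conditions(
        self, low_conc_synergy_experiment
    ):
        res = synergy_kinetics(low_conc_synergy_experiment, 100.0)
        assert res.rate_pred_additive > 0
        assert res.flags["kinetic_additivity"]
        assert res.binding_rate_both == pytest.approx(
            res.binding_rate_a + res.binding_rate_b, rel=0.2
        )

    def test_blocker_a_absent_gives_single_blocker_rate(self):
        cells = synergy_design(
            mg_conc=0.0, voltages=(100.0,), noise_sd=0.0, test_ms=300.0
        )
        exp = generate_experiment(cells, seed=0)
        res = synergy_kinetics(exp, 100.0)
        assert res.rate_a == 0.0
        assert res.rate_both == pytest.approx(res.rate_b, rel=1e-6)

    def test_initial_slope_additivity_in_low_occupancy_limit(
        self, mg_wt, spm_wt, sym100
    ):
        # concentrations at 1% of each blocker's apparent Kd at +100 mV
        v = 100.0
        kd_mg = apparent_kd(StateModel([mg_wt]), v, sym100)
        kd_spm = apparent_kd(StateModel([spm_wt]), v, sym100)
        cond = sym100.with_blocker("Mg", 0.01 * kd_mg).with_blocker(
            "SPM", 0.01 * kd_spm
        )
        # measure -dP_O/dt at t=0 numerically from the relaxation solution
        dt = 1e-9

        def slope(model):
            p0 = np.zeros(model.n_states)
            p0[0] = 1.0
            po = relax_occupancy(model, v, cond, p0, [0.0, dt])[:, 0]
            return (po[0] - po[1]) / dt

        both = slope(StateModel([mg_wt, spm_wt]))
        single = slope(StateModel([mg_wt])) + slope(StateModel([spm_wt]))
        assert both == pytest.approx(single, rel=0.02)
        # and the closed-form initial rate is exactly additive
        assert initial_block_rate(
            StateModel([mg_wt, spm_wt]), v, cond
        ) == pytest.approx(
            initial_block_rate(StateModel([mg_wt]), v, cond)
            + initial_block_rate(StateModel([spm_wt]), v, cond),
            rel=1e-12,
        )

    def test_relative_current_trends_in_asymmetric_potassium(self):
        # 20 mM out / 100 mM in: Mg block deepens, SPM block relieves with
        # depolarization from +20 to +100 mV (punch-through escape of SPM)
        mg = blocker_preset("Mg")
        spm = blocker_preset("SPM")
        cond = SolutionCondition(100.0, 20.0, {"Mg": 0.0, "SPM": 0.0})
        volts = np.arange(20.0, 101.0, 10.0)
        f_mg = [
            1.0 / (1.0 + 1e-3 / apparent_kd(StateModel([mg]), v, cond))
            for v in volts
        ]
        f_spm = [
            1.0 / (1.0 + 1e-5 / apparent_kd(StateModel([spm]), v, cond))
            for v in volts
        ]
        assert np.all(np.diff(f_mg) < 0)
        assert np.all(np.diff(f_spm) > 0)
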