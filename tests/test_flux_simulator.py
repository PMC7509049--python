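"""Two-compartment kinetic model: conservation, fixed points, events."""

import numpy as np
import pytest

from mitoperm.flux_simulator import (
    FluxScenario,
    InitialAmounts,
    RateParameters,
    dimer_constant_from_free_energy,
    resuspension_event,
    simulate,
    speciate_pool,
    uncoupling_event,
)
from mitoperm.synthetic_data import make_flux_truthcase


def _symmetric_scenario(potential=-61.5):
    return FluxScenario(
        volume_out=1.0e-3,
        volume_in=1.0e-3,
        pH_out=7.2,
        pH_in=7.2,
        membrane_potential_program=((0.0, potential),),
        pKa=4.2,
    )


class TestSpeciatePool:
    def test_mass_balance_and_equilibria(self):
        c_ha, c_z, c_d = speciate_pool(1e-3, 8.0, 4.2, 1e3)
        assert c_ha + c_z + 2 * c_d == pytest.approx(1e-3, rel=1e-12)
        assert c_z / c_ha == pytest.approx(10.0 ** (8.0 - 4.2), rel=1e-12)
        assert c_d == pytest.approx(1e3 * c_z**2, rel=1e-12)

    def test_no_dimerisation_limit(self):
        c_ha, c_z, c_d = speciate_pool(1e-3, 7.0, 7.0, 0.0)
        assert c_d == 0.0
        assert c_ha == pytest.approx(c_z)

    def test_dimer_constant_from_pairing_free_energy(self):
        # endergonic pairing => K < 1; zero free energy => K = 1
        assert dimer_constant_from_free_energy(0.0) == 1.0
        assert dimer_constant_from_free_energy(16.0, 298.15) < 1.0


class TestSimulate:
    def test_all_rates_zero_keeps_state_constant(self):
        scenario = _symmetric_scenario()
        rates = RateParameters(
            k_cation_perm=0.0, k_hydrolysis=0.0, K_dimer=0.0,
            k_dimer_perm=0.0,
        )
        init = InitialAmounts(ester_out=1e-8, acid_in=2e-9)
        tr = simulate(scenario, rates, init, np.linspace(0, 100, 11))
        assert np.allclose(tr.ester_out, 1e-8)
        assert np.allclose(tr.pool_in, 2e-9)

    def test_cation_steady_state_is_the_nernst_ratio(self):
        """Pure cation permeation at -61.5 mV and equal volumes settles at
        a ~10-fold inside:outside concentration ratio."""
        scenario = _symmetric_scenario(-61.5)
        rates = RateParameters(
            k_cation_perm=0.5, k_hydrolysis=0.0, K_dimer=0.0,
            k_dimer_perm=0.0,
        )
        init = InitialAmounts(ester_out=1e-8)
        tr = simulate(scenario, rates, init, np.linspace(0, 300, 16))
        ratio = (tr.ester_in[-1] / scenario.volume_in) / (
            tr.ester_out[-1] / scenario.volume_out
        )
        assert ratio == pytest.approx(10.0, rel=0.01)

    @pytest.mark.parametrize("regime", ["uncoupled", "lock_in", "dimer_leak"])
    def test_total_phosphonium_conserved(self, regime):
        tc = make_flux_truthcase(regime, seed=3)
        tr = simulate(tc.scenario, tc.rates, tc.initial,
                      np.linspace(0, 2000, 21))
        total = tr.total_phosphonium()
        assert np.max(np.abs(total - total[0])) / total[0] <= 1e-8

    def test_detailed_balance_without_driving_forces(self):
        tc = make_flux_truthcase("uncoupled", seed=5)
        tr = simulate(tc.scenario, tc.rates, tc.initial,
                      np.linspace(0, 2000, 21))
        v_out, v_in = tc.scenario.volume_out, tc.scenario.volume_in
        assert (tr.ester_in[-1] / v_in) / (
            tr.ester_out[-1] / v_out
        ) == pytest.approx(1.0, rel=1e-6)
        assert (tr.pool_in[-1] / v_in) / (
            tr.pool_out[-1] / v_out
        ) == pytest.approx(1.0, rel=1e-6)

    def test_lock_in_regime_traps_all_hydrolysed_material(self):
        tc = make_flux_truthcase("lock_in", seed=1)
        tr = simulate(tc.scenario, tc.rates, tc.initial,
                      np.linspace(0, 4000, 21))
        assert tr.pool_in[-1] == pytest.approx(
            tc.expected["matrix_acid_pool"], rel=1e-4
        )
        # matrix acid never decreases while ester remains (lock-in limit)
        assert np.all(np.diff(tr.pool_in) >= -1e-16)

    def test_dimer_leak_regime_reaches_conserved_pool_partitioning(self):
        tc = make_flux_truthcase("dimer_leak", seed=2)
        tr = simulate(tc.scenario, tc.rates, tc.initial,
                      np.linspace(0, 6000, 31))
        fraction = tr.pool_in[-1] / (tr.pool_in[-1] + tr.pool_out[-1])
        assert fraction < 0.01
        assert fraction == pytest.approx(
            tc.expected["matrix_acid_fraction"], rel=0.02
        )

    def test_negative_initial_amounts_rejected(self):
        with pytest.raises(ValueError):
            InitialAmounts(ester_out=-1e-9)

    def test_unsorted_grid_rejected(self):
        tc = make_flux_truthcase("uncoupled", seed=1)
        with pytest.raises(ValueError):
            simulate(tc.scenario, tc.rates, tc.initial,
                     np.array([0.0, 2.0, 1.0]))

    def test_solution_insensitive_to_grid_density(self):
        tc = make_flux_truthcase("dimer_leak", seed=4)
        coarse = simulate(tc.scenario, tc.rates, tc.initial,
                          np.linspace(0, 500, 11))
        fine = simulate(tc.scenario, tc.rates, tc.initial,
                        np.linspace(0, 500, 101))
        assert fine.pool_in[-1] == pytest.approx(
            coarse.pool_in[-1], rel=1e-7
        )


def _loaded_acid_setup():
    """Matrix pre-loaded with acid; dimer pathway dominant over the trace
    protonated-cation pathway."""
    scenario = FluxScenario(
        volume_out=2.0e-3,
        volume_in=1.0e-6,
        pH_out=7.2,
        pH_in=8.0,
        membrane_potential_program=((0.0, -160.0),),
        pKa=2.5,
    )
    rates = RateParameters(
        k_cation_perm=0.05, k_hydrolysis=0.0, K_dimer=1.0e4,
        k_dimer_perm=0.5,
    )
    init = InitialAmounts(acid_in=5.0e-9)
    return scenario, rates, init


class TestUncoupling:
    def test_event_at_start_equals_zero_potential_throughout(self):
        scenario, rates, init = _loaded_acid_setup()
        grid = np.linspace(0, 100, 11)
        uncoupled = uncoupling_event(scenario, rates, init, grid, 0.0)
        flat = simulate(
            scenario.model_copy(
                update={"membrane_potential_program": ((0.0, 0.0),)}
            ),
            rates, init, grid,
        )
        assert np.allclose(uncoupled.pool_in, flat.pool_in, rtol=1e-9)
        assert np.allclose(uncoupled.ester_in, flat.ester_in, rtol=1e-9)

    def test_acid_efflux_rate_unchanged_when_dimer_pathway_dominates(self):
        """Efflux of the matrix acid proceeds through the neutral dimer, so
        collapsing the potential changes its initial decay rate by <5%."""
        scenario, rates, init = _loaded_acid_setup()
        dt = 0.5
        grid = np.array([0.0, dt])
        energized = simulate(scenario, rates, init, grid)
        uncoupled = uncoupling_event(scenario, rates, init, grid, 0.0)
        rate_on = (init.acid_in - energized.pool_in[-1]) / dt
        rate_off = (init.acid_in - uncoupled.pool_in[-1]) / dt
        assert rate_on > 0 and rate_off > 0
        assert abs(rate_on - rate_off) / rate_on < 0.05

    def test_matrix_ester_strictly_decreases_after_uncoupling(self):
        scenario = FluxScenario(
            volume_out=2.0e-3, volume_in=1.0e-6,
            membrane_potential_program=((0.0, -160.0),), pKa=2.5,
        )
        rates = RateParameters(
            k_cation_perm=0.5, k_hydrolysis=0.0, K_dimer=0.0,
            k_dimer_perm=0.0,
        )
        init = InitialAmounts(ester_out=1e-8)
        # window ends before the zero-potential equilibrium is reached, so
        # the efflux is still resolvable above floating-point noise
        grid = np.linspace(0.0, 212.0, 54)
        tr = uncoupling_event(scenario, rates, init, grid, 200.0)
        after = tr.ester_in[grid > 200.0]
        assert np.all(np.diff(after) < 0)
        assert after[-1] < 0.1 * after[0]


class TestResuspension:
    def test_control_cation_returns_to_nernst_against_fresh_medium(self):
        scenario = FluxScenario(
            volume_out=1.0e-3, volume_in=1.0e-3, pH_out=7.2, pH_in=7.2,
            membrane_potential_program=((0.0, -61.5),), pKa=4.2,
        )
        rates = RateParameters(
            k_cation_perm=0.5, k_hydrolysis=0.0, K_dimer=0.0,
            k_dimer_perm=0.0,
        )
        init = InitialAmounts(ester_out=1e-8)
        grid = np.linspace(0, 1200, 61)
        tr = resuspension_event(scenario, rates, init, grid, 600.0)
        ratio = (tr.ester_in[-1] / scenario.volume_in) / (
            tr.ester_out[-1] / scenario.volume_out
        )
        assert ratio == pytest.approx(10.0, rel=0.01)

    def test_matrix_acid_lost_despite_maintained_potential(self):
        scenario, rates, init = _loaded_acid_setup()
        grid = np.linspace(0, 600, 61)
        tr = resuspension_event(scenario, rates, init, grid, 300.0)
        after = tr.pool_in[grid > 300.0]
        assert after[-1] < after[0]
        assert tr.pool_in[-1] < 0.5 * init.acid_in

    def test_resuspension_equivalent_to_zeroing_external_state(self):
        scenario, rates, init = _loaded_acid_setup()
        grid = np.linspace(0, 200, 21)
        tr = resuspension_event(scenario, rates, init, grid, 100.0)
        first = simulate(scenario, rates, init,
                         np.linspace(0, 100, 11))
        carried = InitialAmounts(ester_in=max(first.ester_in[-1], 0.0),
                                 acid_in=max(first.pool_in[-1], 0.0))
        second = simulate(scenario, rates, carried,
                          np.linspace(0, 100, 11))
        assert tr.pool_in[-1] == pytest.approx(
            second.pool_in[-1], rel=1e-8
        )
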