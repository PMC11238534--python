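"""The mandatory-coupling equilibrium model: forward maps and fitting."""

import math

import numpy as np
import pytest

from thermocap import (
    EquilibriumParams,
    R_KCAL,
    T_REF,
    alternate_solution,
    apparent_cp,
    apparent_enthalpy,
    apparent_free_energy,
    fit_equilibrium,
    keq,
    summarize_equilibrium,
)
from thermocap import datasets
from thermocap.errors import InsufficientDataError
from thermocap.synthetic import gen_itc_series

TEMPS = np.arange(283.0, 314.0, 5.0)


def _random_params(rng):
    dh_eq = rng.uniform(2.0, 30.0)
    t_mid = rng.uniform(270.0, 330.0)
    return EquilibriumParams(dh_eq=dh_eq, ds_eq=dh_eq / t_mid, dh_b=rng.uniform(-10.0, 10.0))


class TestForwardModel:
    def test_keq_unity_at_transition(self):
        params = EquilibriumParams(dh_eq=15.0, ds_eq=15.0 / 300.0, dh_b=0.0)
        assert keq(params, 300.0) == pytest.approx(1.0)

    def test_keq_ligand0(self, ligand0_params):
        # dG_eq ~ 0.30 kcal/mol at 298 K -> K_eq ~ 0.60
        assert keq(ligand0_params, T_REF) == pytest.approx(0.60, abs=0.01)

    def test_keq_vanishes_for_large_uphill_equilibrium(self):
        params = EquilibriumParams(dh_eq=500.0, ds_eq=0.059, dh_b=0.0)
        assert keq(params, 298.15) < 1e-200

    def test_enthalpy_limits(self):
        params = EquilibriumParams(dh_eq=17.5, ds_eq=0.058, dh_b=2.0)
        assert apparent_enthalpy(params, 150.0) == pytest.approx(params.dh_b, abs=1e-6)
        assert apparent_enthalpy(params, 2000.0) == pytest.approx(
            params.dh_b - params.dh_eq, abs=1e-3
        )

    def test_enthalpy_monotone_decreasing_with_asymptotes(self):
        params = EquilibriumParams(dh_eq=17.57, ds_eq=0.0582, dh_b=1.5)
        grid = np.linspace(200.0, 500.0, 301)
        values = apparent_enthalpy(params, grid)
        assert np.all(np.diff(values) < 0)
        assert np.all(values < params.dh_b)
        assert np.all(values > params.dh_b - params.dh_eq)

    def test_cp_zero_without_equilibrium_enthalpy(self):
        params = EquilibriumParams(dh_eq=0.0, ds_eq=0.01, dh_b=3.0)
        assert apparent_cp(params, 298.15) == 0.0

    def test_cp_dip_at_transition_temperature(self):
        params = EquilibriumParams(dh_eq=17.5, ds_eq=0.0575, dh_b=0.0)
        t_mid = params.dh_eq / params.ds_eq
        expected = -params.dh_eq**2 / (4 * R_KCAL * t_mid**2)
        assert apparent_cp(params, t_mid) == pytest.approx(expected, rel=1e-12)

    def test_cp_at_average_benchmark_parameters(self):
        params = EquilibriumParams(dh_eq=17.57, ds_eq=0.0582, dh_b=0.0)
        assert apparent_cp(params, T_REF) == pytest.approx(-0.42, abs=0.01)

    def test_cp_equals_enthalpy_derivative_at_average_parameters(self):
        params = EquilibriumParams(dh_eq=17.57, ds_eq=0.0582, dh_b=0.0)
        h = 0.01
        fd = (apparent_enthalpy(params, T_REF + h) - apparent_enthalpy(params, T_REF - h)) / (2 * h)
        cp = apparent_cp(params, T_REF)
        assert abs(fd - cp) / abs(cp) < 1e-6

    def test_cp_equals_enthalpy_derivative_randomized(self):
        """1000 random parameter sets: analytic dCp_app vs central difference."""
        rng = np.random.default_rng(99)
        h = 0.01
        for _ in range(1000):
            params = _random_params(rng)
            t = rng.uniform(270.0, 330.0)
            fd = (apparent_enthalpy(params, t + h) - apparent_enthalpy(params, t - h)) / (2 * h)
            cp = apparent_cp(params, t)
            assert abs(fd - cp) <= 1e-6 * max(abs(cp), 1e-9)

    def test_free_energy_reduces_to_dg_b_without_inactive_state(self):
        params = EquilibriumParams(dh_eq=100.0, ds_eq=0.0, dh_b=-5.0, ds_b=0.02)
        assert apparent_free_energy(params, 298.15) == pytest.approx(
            -5.0 - 298.15 * 0.02, abs=1e-10
        )

    def test_nonpositive_temperature_rejected(self, ligand0_params):
        for func in (keq, apparent_enthalpy, apparent_cp, apparent_free_energy):
            with pytest.raises(ValueError):
                func(ligand0_params, -1.0)


class TestAlternateSolution:
    def test_involution(self):
        params = EquilibriumParams(17.5, 0.0575, 1.5, 0.0477)
        twice = alternate_solution(alternate_solution(params))
        assert twice.dh_eq == pytest.approx(params.dh_eq)
        assert twice.ds_eq == pytest.approx(params.ds_eq)
        assert twice.dh_b == pytest.approx(params.dh_b)
        assert twice.ds_b == pytest.approx(params.ds_b)

    def test_observables_identical_between_solutions(self):
        for ligand in "012345":
            params = datasets.equilibrium_params(ligand)
            mirror = alternate_solution(params)
            for t in TEMPS:
                assert apparent_enthalpy(mirror, t) == pytest.approx(
                    apparent_enthalpy(params, t), abs=1e-9
                )
                assert apparent_free_energy(mirror, t) == pytest.approx(
                    apparent_free_energy(params, t), abs=1e-9
                )
                assert apparent_cp(mirror, t) == pytest.approx(
                    apparent_cp(params, t), abs=1e-9
                )


class TestFitEquilibrium:
    def test_noise_free_recovery(self, ligand3_params):
        series = gen_itc_series(ligand3_params, noise_sd=0.0, seed=0)
        res = fit_equilibrium(series)
        assert res.params.dh_eq == pytest.approx(17.86, abs=1e-6)
        assert res.params.ds_eq == pytest.approx(0.0601, abs=1e-8)
        assert res.params.dh_b == pytest.approx(3.69, abs=1e-6)
        assert math.isnan(res.params.ds_b)
        assert res.ds_b_source == "undefined"

    def test_noisy_recovery_within_ten_percent(self, ligand3_params):
        series = gen_itc_series(ligand3_params, noise_sd=0.1, seed=42)
        res = fit_equilibrium(series)
        assert abs(res.params.dh_eq - 17.86) / 17.86 < 0.10

    def test_ds_b_solved_from_free_energy_reference(self, ligand3_params):
        series = gen_itc_series(ligand3_params, noise_sd=0.0, seed=0)
        res = fit_equilibrium(series, dg_app_ref=(T_REF, -12.54))
        assert res.params.ds_b == pytest.approx(0.0559, abs=5e-4)
        assert res.ds_b_source == "reference"
        assert res.predict_free_energy(T_REF) == pytest.approx(-12.54, abs=1e-9)

    def test_branch_selection_and_alternate(self, ligand3_params):
        series = gen_itc_series(ligand3_params, noise_sd=0.0, seed=0)
        positive = fit_equilibrium(series, branch="positive")
        negative = fit_equilibrium(series, branch="negative")
        assert positive.params.dh_eq > 0 > negative.params.dh_eq
        mirrored = positive.alternate()
        assert mirrored.params.dh_eq == pytest.approx(negative.params.dh_eq, abs=1e-6)
        assert mirrored.params.dh_b == pytest.approx(negative.params.dh_b, abs=1e-6)

    def test_weighted_fit_uses_uncertainties(self, ligand3_params):
        series = gen_itc_series(ligand3_params, noise_sd=0.05, seed=7)
        res = fit_equilibrium(series)
        assert res.converged
        # rss is in weighted (chi-square) units: ~dof for well-matched sds
        assert res.rss < 20.0
        assert np.max(np.abs(res.resid)) < 0.2  # raw residuals ~ 4 sd

    def test_insufficient_points_rejected(self):
        from thermocap import ITCSeries

        with pytest.raises(InsufficientDataError):
            fit_equilibrium(ITCSeries([283.0, 298.0], [-5.0, -6.0]))

    def test_summary_mentions_key_quantities(self, ligand3_params):
        series = gen_itc_series(ligand3_params, noise_sd=0.0, seed=0)
        text = fit_equilibrium(series, dg_app_ref=(T_REF, -12.54)).summary()
        assert "dH_eq" in text and "dG_app" in text


class TestSummary:
    def test_benchmark_mean_and_sem(self):
        params = [datasets.equilibrium_params(l) for l in "012345"]
        table = summarize_equilibrium(params)
        assert table.loc["dh_eq", "mean"] == pytest.approx(17.565, abs=1e-9)
        assert table.loc["dh_eq", "sem"] == pytest.approx(0.13, abs=0.005)
        assert table.loc["ds_eq", "mean"] == pytest.approx(0.0582, abs=5e-5)
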