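"""Ensemble geometry: distances, histograms, superposition, RMSF, B-factors."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import spearmanr

from thermocap import (
    CoordinateEnsemble,
    binned_energy_profile,
    ca_rmsd,
    distance_distribution,
    end_to_end_series,
    rmsf_from_bfactors,
    rmsf_per_atom,
    rmsf_per_residue,
    state_fractions,
    superpose_ensemble,
)
from thermocap.errors import (
    AlignmentError,
    InsufficientDataError,
    SelectionError,
    UnalignedEnsembleWarning,
)
from thermocap.synthetic import (
    TwoStateSpec,
    gen_base_structure,
    gen_ensemble,
    gen_two_state_trajectory,
)


def _two_atom_ensemble(coords):
    coords = np.asarray(coords, float)
    return CoordinateEnsemble(
        coords=coords,
        atom_names=np.array(["C1", "C2"]),
        res_ids=np.array([1, 1]),
        res_names=np.array(["LIG", "LIG"]),
        chains=np.array(["A", "A"]),
    )


class TestEndToEnd:
    def test_three_four_five_triangle(self):
        ens = _two_atom_ensemble([[[0.0, 0.0, 0.0], [3.0, 4.0, 0.0]]])
        np.testing.assert_allclose(end_to_end_series(ens, "C1", "C2"), [5.0])

    def test_translation_invariance(self, rng):
        base = rng.normal(size=(20, 2, 3))
        shifted = base + rng.normal(size=(20, 1, 3))
        d0 = end_to_end_series(_two_atom_ensemble(base), "C1", "C2")
        d1 = end_to_end_series(_two_atom_ensemble(shifted), "C1", "C2")
        np.testing.assert_allclose(d0, d1, atol=1e-12)

    def test_two_state_sample_mean_between_state_means(self):
        spec = TwoStateSpec(inactive_fraction=0.4)
        traj = gen_two_state_trajectory(spec, seed=1, with_ensemble=True)
        distances = end_to_end_series(traj.ensemble, "C1", "C2")
        np.testing.assert_allclose(distances, traj.distances, atol=1e-12)
        assert spec.compact_mean < distances.mean() < spec.extended_mean

    def test_ambiguous_selector_rejected(self):
        ens = _two_atom_ensemble([[[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]])
        with pytest.raises(SelectionError):
            end_to_end_series(ens, "1/*", "C2")  # matches both atoms
        with pytest.raises(SelectionError):
            end_to_end_series(ens, "CX", "C2")  # matches none


class TestDistanceDistribution:
    def test_delta_distribution(self):
        dist = distance_distribution(np.full(50, 5.2), bin_width=0.5, range=(3, 20))
        assert dist.probabilities.max() == 1.0
        assert dist.probabilities.sum() == pytest.approx(1.0)

    def test_normalization_and_overflow(self, rng):
        samples = rng.uniform(0.0, 30.0, 500)
        dist = distance_distribution(samples, bin_width=0.5, range=(3, 20))
        assert dist.probabilities.sum() == pytest.approx(1.0)
        assert dist.n_overflow == np.sum((samples < 3) | (samples >= 20.0))

    def test_two_state_trajectory_is_bimodal(self):
        traj = gen_two_state_trajectory(TwoStateSpec(), temperature=298.15, seed=0)
        modes = distance_distribution(traj.distances).modes(min_prob=0.01, min_separation=2.0)
        assert len(modes) == 2
        assert abs(modes[0] - 5.5) < 1.0
        assert modes[1] > 11.0

    def test_empty_input_rejected(self):
        with pytest.raises(InsufficientDataError):
            distance_distribution(np.array([]))


class TestStateFractions:
    def test_all_compact(self):
        assert state_fractions(np.full(10, 5.0), 8.0, 11.0) == (1.0, 0.0, 0.0)

    def test_hand_counted_thirds(self):
        fracs = state_fractions(np.array([7.0, 9.0, 12.0]), 8.0, 11.0)
        assert fracs == pytest.approx((1 / 3, 1 / 3, 1 / 3))

    def test_recovers_generator_inactive_fraction(self):
        # classification cut at the inter-state midpoint (9 A), where the
        # compact (5.5 +/- 0.7) and extended (12.5 +/- 1.8) basins barely leak
        traj = gen_two_state_trajectory(TwoStateSpec(inactive_fraction=0.4), seed=8)
        f_compact, f_mid, f_extended = state_fractions(traj.distances, 8.0, 9.0)
        assert abs(f_extended - 0.4) < 0.03
        assert f_compact + f_mid + f_extended == pytest.approx(1.0)

    def test_inverted_cuts_rejected(self):
        with pytest.raises(ValueError):
            state_fractions(np.array([5.0]), 11.0, 8.0)


class TestBinnedEnergyProfile:
    def test_zero_energies(self):
        profile = binned_energy_profile([5.0, 5.1, 12.0], [0.0, 0.0, 0.0])
        occupied = profile.mean_energy[profile.occupied]
        np.testing.assert_allclose(occupied, 0.0)
        assert np.all(np.isnan(profile.mean_energy[~profile.occupied]))

    def test_identity_signal(self, rng):
        d = rng.uniform(4.0, 18.0, 2000)
        profile = binned_energy_profile(d, d)
        occ = profile.occupied
        # mean distance per bin stays within that bin
        assert np.all(np.abs(profile.mean_energy[occ] - profile.bin_centers[occ]) <= 0.25)

    def test_recovers_generator_slope_signs(self):
        traj = gen_two_state_trajectory(TwoStateSpec(), seed=4)
        for energies, expected_sign in (
            (traj.intra_energies, -1.0),
            (traj.solvent_energies, +1.0),
        ):
            profile = binned_energy_profile(traj.distances, energies)
            occ = profile.occupied
            slope = np.polyfit(profile.bin_centers[occ], profile.mean_energy[occ], 1)[0]
            assert np.sign(slope) == expected_sign

    def test_length_mismatch_rejected(self):
        with pytest.raises(AlignmentError):
            binned_energy_profile([5.0, 6.0], [1.0])


class TestSuperposition:
    def test_single_frame_average_is_frame(self):
        base = gen_base_structure(8)
        aligned, average = superpose_ensemble(base, selection="CA")
        np.testing.assert_allclose(average, base.coords[0], atol=1e-12)
        assert ca_rmsd(aligned.coords[0], base.coords[0]) < 1e-9

    def test_rigid_rotations_removed(self, rng):
        base = gen_base_structure(10)
        frames = []
        for _ in range(12):
            rot = Rotation.random(rng=rng).as_matrix()
            frames.append(base.coords[0] @ rot + rng.normal(0, 5.0, 3))
        ens = base.with_coords(np.stack(frames))
        aligned, _ = superpose_ensemble(ens, selection="CA")
        for f in range(1, aligned.n_frames):
            assert ca_rmsd(aligned.coords[0], aligned.coords[f]) < 1e-6

    def test_average_recovers_noisy_base(self):
        base = gen_base_structure(30)
        ens = gen_ensemble(base, 0.3, frames=500, seed=21)
        _, average = superpose_ensemble(ens, selection="CA")
        assert ca_rmsd(average, base.coords[0]) < 0.05

    def test_objective_monotone_nonincreasing(self):
        base = gen_base_structure(15)
        ens = gen_ensemble(base, 0.5, frames=50, seed=3, rigid_motions=True)
        _, _, history = superpose_ensemble(ens, selection="CA", return_history=True)
        assert all(b <= a + 1e-9 for a, b in zip(history, history[1:]))

    def test_too_few_atoms_rejected(self):
        ens = _two_atom_ensemble([[[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]])
        with pytest.raises(SelectionError):
            superpose_ensemble(ens, selection=None)


class TestCaRmsd:
    def test_identical_structures(self):
        base = gen_base_structure(12)
        assert ca_rmsd(base.coords[0], base.coords[0]) == pytest.approx(0.0, abs=1e-12)

    def test_rotation_is_removed(self, rng):
        base = gen_base_structure(12).coords[0]
        rotated = base @ Rotation.random(rng=rng).as_matrix() + [3.0, -2.0, 1.0]
        assert ca_rmsd(base, rotated) < 1e-9

    def test_single_atom_perturbation_bound(self):
        coords = np.random.default_rng(0).normal(size=(100, 3)) * 10
        perturbed = coords.copy()
        perturbed[0] += [1.0, 0.0, 0.0]
        value = ca_rmsd(coords, perturbed)
        assert 0.0 < value <= 0.1  # sqrt(1/100) before optimal refit

    def test_count_mismatch_rejected(self):
        with pytest.raises(AlignmentError):
            ca_rmsd(np.zeros((5, 3)), np.zeros((6, 3)))


class TestRmsf:
    def test_static_ensemble_is_zero(self):
        base = gen_base_structure(5)
        ens = base.with_coords(np.repeat(base.coords, 20, axis=0))
        assert rmsf_per_residue(ens).max() < 1e-12

    def test_oscillating_atom_closed_form(self):
        base = gen_base_structure(5)
        coords = np.repeat(base.coords, 10, axis=0)
        coords[::2, 0, 0] += 1.0
        coords[1::2, 0, 0] -= 1.0
        _, rmsf = rmsf_per_atom(base.with_coords(coords))
        assert rmsf[0] == pytest.approx(1.0)  # alternating +/-1 about the mean
        np.testing.assert_allclose(rmsf[1:], 0.0, atol=1e-12)

    def test_prescribed_profile_rank_recovered(self):
        base = gen_base_structure(30)
        sds = np.linspace(0.1, 1.0, 30)
        ens = gen_ensemble(base, sds, frames=300, seed=6)
        rmsf = rmsf_per_residue(ens, selection="backbone")
        rho = spearmanr(sds, rmsf.to_numpy()).statistic
        assert rho > 0.95

    def test_unsuperposed_ensemble_warns(self):
        base = gen_base_structure(10)
        ens = gen_ensemble(base, 0.2, frames=30, seed=2, rigid_motions=True)
        with pytest.warns(UnalignedEnsembleWarning):
            rmsf_per_residue(ens)


class TestBfactors:
    def test_zero_maps_to_zero(self):
        assert rmsf_from_bfactors(0.0) == 0.0

    def test_unit_point_of_the_conversion(self):
        assert rmsf_from_bfactors(8 * np.pi**2 / 3) == pytest.approx(1.0, abs=1e-15)

    def test_direct_formula_value(self):
        assert rmsf_from_bfactors(20.0) == pytest.approx(np.sqrt(60.0 / (8 * np.pi**2)))
        assert rmsf_from_bfactors(20.0) == pytest.approx(0.872, abs=5e-4)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            rmsf_from_bfactors(np.array([1.0, -0.5]))


class TestPdbRoundTrip:
    def test_multi_model_pdb(self, tmp_path):
        base = gen_base_structure(6)
        base.b_factors = np.linspace(10.0, 30.0, base.n_atoms)
        ens = gen_ensemble(base, 0.3, frames=4, seed=5)
        path = tmp_path / "ens.pdb"
        ens.to_pdb(path)
        back = CoordinateEnsemble.from_pdb(path)
        assert back.n_frames == 4
        assert back.n_atoms == ens.n_atoms
        np.testing.assert_allclose(back.coords, ens.coords, atol=1.5e-3)  # PDB 3-decimals
        np.testing.assert_array_equal(back.res_ids, ens.res_ids)
        np.testing.assert_array_equal(back.atom_names, ens.atom_names)
        np.testing.assert_allclose(back.b_factors, ens.b_factors, atol=5e-3)
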