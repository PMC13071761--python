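"""Superposition, fluctuation statistics and common-eigenspace PCA."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ptmgate.model_io import StatePair, Trajectory, ValidationError
from ptmgate.superpose_pca import (
    DegenerateGeometryError,
    PCAResult,
    centroid_shift,
    combined_pca,
    kabsch_superpose,
    mode_residue_contributions,
    radius_of_gyration,
    rmsf,
)
from ptmgate.synthetic import (
    CorrelationRecipe,
    FluctuationModel,
    make_reference_structure,
    make_synthetic_system,
    sample_fluctuation_trajectory,
)


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(6, 3))
        aligned, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(aligned, pts, atol=1e-12)

    def test_rigid_motion_removed(self):
        pts = np.random.default_rng(1).normal(size=(7, 3))
        rot = Rotation.from_euler("z", 90, degrees=True)
        moved = rot.apply(pts) + np.array([1.0, 2.0, 3.0])
        aligned, rmsd = kabsch_superpose(moved, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(aligned, pts, atol=1e-9)

    def test_matches_rotation_grid_oracle(self):
        """RMSD equals exhaustive minimisation over a refined rotation grid."""
        rng = np.random.default_rng(2)
        mobile = rng.normal(size=(5, 3))
        reference = mobile + 0.1 * rng.normal(size=(5, 3))
        _, rmsd = kabsch_superpose(mobile, reference)

        mob_c = mobile - mobile.mean(axis=0)
        ref_c = reference - reference.mean(axis=0)

        def grid_min(center: np.ndarray, width: float, steps: int) -> tuple:
            axes = [np.linspace(c - width, c + width, steps) for c in center]
            grids = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
            mats = Rotation.from_euler("zyx", grids).as_matrix()
            rotated = np.einsum("nij,kj->nki", mats, mob_c)
            costs = np.sqrt(np.mean(np.sum((rotated - ref_c) ** 2, axis=2), axis=1))
            best = int(np.argmin(costs))
            return grids[best], float(costs[best])

        center, best = np.zeros(3), np.inf
        width = np.pi
        for steps in (25, 15, 15, 15):
            center, best = grid_min(center, width, steps)
            width = width * 2.5 / steps
        assert rmsd == pytest.approx(best, abs=1e-4)
        assert rmsd <= best + 1e-12  # analytic solution is the true minimum

    def test_degenerate_geometry_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line)
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line[:2], line[:2])


class TestRMSF:
    def test_constant_trajectory_zero(self):
        system = make_synthetic_system(4)
        ref = make_reference_structure(system, seed=0)
        traj = Trajectory(system, np.repeat(ref[None], 5, axis=0))
        np.testing.assert_allclose(rmsf([traj], "all"), 0.0, atol=1e-12)

    def test_two_point_alternation(self):
        system = make_synthetic_system(4)
        ref = make_reference_structure(system, seed=0)
        coords = np.repeat(ref[None], 4, axis=0)
        coords[1::2, 2, 0] += 2.0  # one atom alternates x by 2 nm
        traj = Trajectory(system, coords)
        values = rmsf([traj], "all", fit=False)
        assert values[2] == pytest.approx(1.0)
        assert np.all(values[[0, 1, 3]] == 0.0)

    def test_isotropic_gaussian_moment(self):
        """RMSF of an isotropic 3D Gaussian is sigma * sqrt(3)."""
        system = make_synthetic_system(6)
        ref = make_reference_structure(system, seed=0)
        sd = np.array([0.02, 0.03, 0.04, 0.05, 0.06, 0.07])
        model = FluctuationModel(
            system=system, reference=ref,
            recipe=CorrelationRecipe(n_residues=6, sd=sd), seed=1,
        )
        traj = sample_fluctuation_trajectory(model, 20000)
        values = rmsf([traj], "all", fit=False)
        np.testing.assert_allclose(values, sd * np.sqrt(3), rtol=0.02)


class TestRadiusOfGyration:
    def test_two_equal_masses(self):
        frame = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert radius_of_gyration(frame) == pytest.approx(1.0)

    def test_coincident_atoms(self):
        assert radius_of_gyration(np.zeros((5, 3))) == 0.0

    def test_unit_square(self):
        frame = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
        assert radius_of_gyration(frame) == pytest.approx(np.sqrt(0.5))

    def test_mass_weighted_needs_positive_mass(self):
        with pytest.raises(ValidationError):
            radius_of_gyration(np.zeros((2, 3)), masses=np.zeros(2), mass_weighted=True)


def _pair_from_covariance(cov, n_frames, seeds=(5, 6), n_res=1):
    system = make_synthetic_system(n_res)
    ref = make_reference_structure(system, seed=0)
    trajs = []
    for seed in seeds:
        model = FluctuationModel(
            system=system, reference=ref, covariance=cov, seed=seed
        )
        trajs.append(sample_fluctuation_trajectory(model, n_frames))
    return StatePair([trajs[0]], [trajs[1]], "all")


class TestCombinedPCA:
    def test_identical_frames_zero_eigenvalues(self):
        system = make_synthetic_system(4)
        ref = make_reference_structure(system, seed=0)
        traj = Trajectory(system, np.repeat(ref[None], 5, axis=0))
        pair = StatePair([traj], [traj], "all")
        result = combined_pca(pair)
        np.testing.assert_allclose(result.eigenvalues, 0.0, atol=1e-20)

    def test_single_coordinate_variance(self):
        cov = np.zeros((3, 3))
        cov[0, 0] = 1.0
        pair = _pair_from_covariance(cov, 200)
        result = combined_pca(pair)
        assert result.variance_fractions[0] == pytest.approx(1.0, abs=1e-9)

    def test_known_covariance_recovery(self):
        cov = np.diag([4.0, 1.0, 0.25])
        pair = _pair_from_covariance(cov, 25000)
        result = combined_pca(pair)
        np.testing.assert_allclose(result.eigenvalues, [4.0, 1.0, 0.25], rtol=0.05)

    def test_trace_identity_and_fraction_sum(self):
        system = make_synthetic_system(5)
        ref = make_reference_structure(system, seed=0)
        model = FluctuationModel(
            system=system, reference=ref,
            recipe=CorrelationRecipe(n_residues=5, correlations={(0, 4): 0.5}),
            seed=3,
        )
        pair = StatePair(
            [sample_fluctuation_trajectory(model, 300)],
            [sample_fluctuation_trajectory(
                FluctuationModel(system=system, reference=ref,
                                 recipe=CorrelationRecipe(n_residues=5), seed=4),
                300,
            )],
            "all",
        )
        result = combined_pca(pair)
        assert abs(result.eigenvalues.sum() - result.total_variance) < 1e-9
        assert result.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)
        # orthonormality
        gram = result.eigenvectors.T @ result.eigenvectors
        np.testing.assert_allclose(gram, np.eye(result.n_modes), atol=1e-9)

    def test_rigid_motion_and_frame_order_invariance(self):
        system = make_synthetic_system(6)
        ref = make_reference_structure(system, seed=0)
        model = FluctuationModel(
            system=system, reference=ref,
            recipe=CorrelationRecipe(n_residues=6, correlations={(1, 2): 0.4}),
            seed=7,
        )
        traj_a = sample_fluctuation_trajectory(model, 150)
        model_b = FluctuationModel(
            system=system, reference=ref,
            recipe=CorrelationRecipe(n_residues=6), seed=8,
        )
        traj_b = sample_fluctuation_trajectory(model_b, 150)
        base = combined_pca(StatePair([traj_a], [traj_b], "all"))

        rot = Rotation.from_euler("xyz", [0.3, -1.1, 0.7])
        moved = Trajectory(
            system, rot.apply(traj_a.coordinates.reshape(-1, 3)).reshape(
                traj_a.coordinates.shape
            ) + np.array([1.0, -2.0, 0.5]),
        )
        contaminated = combined_pca(StatePair([moved], [traj_b], "all"))
        np.testing.assert_allclose(
            contaminated.eigenvalues, base.eigenvalues, atol=1e-9
        )

        shuffled = Trajectory(system, traj_a.coordinates[::-1].copy())
        reordered = combined_pca(StatePair([shuffled], [traj_b], "all"))
        np.testing.assert_allclose(reordered.eigenvalues, base.eigenvalues, atol=1e-9)

    def test_reconstruction_with_all_modes(self):
        system = make_synthetic_system(4)
        ref = make_reference_structure(system, seed=0)
        model = FluctuationModel(
            system=system, reference=ref,
            recipe=CorrelationRecipe(n_residues=4, correlations={(0, 1): -0.3}),
            seed=9,
        )
        traj = sample_fluctuation_trajectory(model, 100)
        pair = StatePair([traj], [traj], "all")
        result = combined_pca(pair)
        proj = result.projections[("reduced", 0)]
        reconstructed = proj @ result.eigenvectors.T
        # recompute the centred coordinates the projections came from
        from ptmgate.superpose_pca import align_frames_to_mean

        combined = np.concatenate([traj.coordinates, traj.coordinates])
        aligned = align_frames_to_mean(combined)
        centred = (aligned - aligned.mean(axis=0))[: traj.n_frames].reshape(
            traj.n_frames, -1
        )
        np.testing.assert_allclose(reconstructed, centred, atol=1e-8)


def _result_with_vector(vec: np.ndarray) -> PCAResult:
    vec = vec / np.linalg.norm(vec)
    m = len(vec) // 3
    return PCAResult(
        eigenvalues=np.array([1.0]),
        eigenvectors=vec[:, None],
        variance_fractions=np.array([1.0]),
        projections={},
        mean_structure=np.zeros((m, 3)),
        residue_keys=[("A", i + 1) for i in range(m)],
        total_variance=1.0,
    )


class TestModeContributions:
    def test_dominant_residue_only(self):
        # per-residue |v| magnitudes 0.5, 0.3, 0.1, 0.1
        vec = np.array([0.5, 0, 0, 0.3, 0, 0, 0.1, 0, 0, 0.1, 0, 0])
        contribution = mode_residue_contributions(_result_with_vector(vec), 0, 0.5)
        assert contribution.top_set == [("A", 1)]

    def test_uniform_ties_take_lower_indices(self):
        vec = np.array([0.2, 0, 0] * 4)
        contribution = mode_residue_contributions(_result_with_vector(vec), 0, 0.5)
        assert contribution.top_set == [("A", 1), ("A", 2)]

    def test_single_residue_mode(self):
        vec = np.array([0.0, 1.0, 0.0])
        contribution = mode_residue_contributions(_result_with_vector(vec), 0, 0.5)
        assert contribution.top_set == [("A", 1)]
        assert contribution.contributions[0] == pytest.approx(1.0)

    def test_contributions_sum_to_one(self):
        rng = np.random.default_rng(12)
        vec = rng.normal(size=15)
        contribution = mode_residue_contributions(_result_with_vector(vec), 0, 0.5)
        assert contribution.contributions.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(contribution.contributions >= 0)


class TestCentroidShift:
    def _result_with_projections(self, red, ptm):
        return PCAResult(
            eigenvalues=np.ones(red.shape[1]),
            eigenvectors=np.eye(3 * 1)[:, : red.shape[1]],
            variance_fractions=np.ones(red.shape[1]) / red.shape[1],
            projections={("reduced", 0): red, ("ptm", 0): ptm},
            mean_structure=np.zeros((1, 3)),
            residue_keys=[("A", 1)],
            total_variance=float(red.shape[1]),
        )

    def test_identical_projections_zero_shift(self):
        proj = np.random.default_rng(0).normal(size=(50, 2))
        shifts = centroid_shift(self._result_with_projections(proj, proj.copy()))
        np.testing.assert_allclose(shifts["all"], 0.0, atol=1e-12)

    def test_constant_offset_along_pc1(self):
        proj = np.random.default_rng(1).normal(size=(50, 2))
        shifted = proj + np.array([0.7, 0.0])
        shifts = centroid_shift(self._result_with_projections(proj, shifted))
        np.testing.assert_allclose(shifts["all"], [0.7, 0.0], atol=1e-12)

    def test_generative_mean_shift_recovered(self):
        rng = np.random.default_rng(2)
        n = 4000
        red = rng.normal(size=(n, 2))
        ptm = rng.normal(size=(n, 2)) + np.array([0.3, -0.2])
        shifts = centroid_shift(self._result_with_projections(red, ptm))
        se = np.sqrt(2.0 / n)
        assert abs(shifts["all"][0] - 0.3) < 3 * se
        assert abs(shifts["all"][1] + 0.2) < 3 * se

    def test_missing_state_rejected(self):
        result = self._result_with_projections(
            np.zeros((5, 2)), np.zeros((5, 2))
        )
        del result.projections[("ptm", 0)]
        with pytest.raises(ValidationError, match="missing"):
            centroid_shift(result)
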