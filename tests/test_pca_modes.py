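import numpy as np
import pytest

from mdflex.pca_modes import (
    EnsembleMatrix,
    build_combined_ensemble,
    extreme_structures,
    fit_pca,
    mode_overlap,
    morph,
    project,
    variance_explained,
)
from mdflex.synthetic_data import (
    MotionSpec,
    generate_trajectory,
    interdomain_angle_series,
    motion_for_variances,
)
from mdflex.traj_metrics import Trajectory, kabsch_superpose

from conftest import make_model


def _ensemble_from_rows(rows, n_atoms=None):
    rows = np.asarray(rows, dtype=float)
    n_atoms = rows.shape[1] // 3
    return EnsembleMatrix(matrix=rows, labels=[""] * len(rows),
                          reference=rows[0].reshape(-1, 3),
                          residue_numbers=np.arange(1, n_atoms + 1))


def _rank_one_ensemble(rng, n_atoms=8, a=2.0):
    mean = rng.normal(size=3 * n_atoms)
    v = rng.normal(size=3 * n_atoms)
    v /= np.linalg.norm(v)
    rows = np.stack([mean + a * v, mean - a * v] * 5)
    return _ensemble_from_rows(rows), v, a


class TestBuildEnsemble:
    def test_rigid_trajectory_identical_rows(self, toy_structure):
        traj = Trajectory(coords=np.stack([toy_structure.coords] * 4),
                          atom_meta=toy_structure)
        ens = build_combined_ensemble([traj], toy_structure)
        assert ens.n_frames == 4
        assert np.ptp(ens.matrix, axis=0).max() < 1e-9

    def test_concatenation_and_labels(self, toy_structure):
        traj = Trajectory(coords=np.stack([toy_structure.coords] * 5),
                          atom_meta=toy_structure)
        ens = build_combined_ensemble([traj, traj], toy_structure,
                                      labels=["apo", "bound"])
        assert ens.n_frames == 10
        assert ens.labels == ["apo"] * 5 + ["bound"] * 5

    def test_alignment_removes_planted_global_rotation(self, toy_structure,
                                                       toy_spec, rng):
        motion = MotionSpec(hinge_amplitude=3.0, twist_amplitude=0.0,
                            n_frames=60, seed=4)
        traj, truth = generate_trajectory(toy_structure, motion, toy_spec)
        # contaminate with a random global rigid motion per frame
        contaminated = []
        for frame in traj.coords:
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            ang = rng.uniform(-0.5, 0.5)
            k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                          [-axis[1], axis[0], 0]])
            rot = np.eye(3) + np.sin(ang) * k + (1 - np.cos(ang)) * (k @ k)
            contaminated.append(frame @ rot.T + rng.uniform(-5, 5, size=3))
        dirty = Trajectory(coords=np.array(contaminated),
                           atom_meta=toy_structure)
        ens_clean = build_combined_ensemble([traj], toy_structure)
        ens_dirty = build_combined_ensemble([dirty], toy_structure)
        var_clean = ens_clean.matrix.var(axis=0).sum()
        var_dirty = ens_dirty.matrix.var(axis=0).sum()
        assert var_dirty == pytest.approx(var_clean, rel=1e-6)

    def test_topology_mismatch(self, toy_structure):
        small = make_model([(i, "GLY", "CA", (i, 0, 0)) for i in range(1, 5)])
        traj = Trajectory(coords=np.stack([small.coords] * 3), atom_meta=small)
        with pytest.raises(ValueError):
            build_combined_ensemble([traj], toy_structure)


class TestFitPCA:
    def test_rank_one_recovery(self, rng):
        ens, v, a = _rank_one_ensemble(rng)
        model = fit_pca(ens)
        assert abs(model.eigenvectors[:, 0] @ v) == pytest.approx(1.0, abs=1e-9)
        # two-point +-a ensemble: variance = a^2 * n/(n-1)
        n = ens.n_frames
        assert model.eigenvalues[0] == pytest.approx(a * a * n / (n - 1), rel=1e-9)
        assert np.all(model.eigenvalues[1:] < 1e-9)

    def test_trace_conservation(self, rng):
        rows = rng.normal(size=(20, 12))
        ens = _ensemble_from_rows(rows)
        model = fit_pca(ens)
        assert model.eigenvalues.sum() == pytest.approx(
            rows.var(axis=0, ddof=1).sum(), rel=1e-9)

    def test_orthonormal_columns(self, rng):
        ens = _ensemble_from_rows(rng.normal(size=(15, 9)))
        model = fit_pca(ens)
        gram = model.eigenvectors.T @ model.eigenvectors
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-8)

    def test_frame_order_invariance(self, rng):
        rows = rng.normal(size=(30, 12))
        ens1 = _ensemble_from_rows(rows)
        ens2 = _ensemble_from_rows(rows[::-1])
        m1, m2 = fit_pca(ens1), fit_pca(ens2)
        np.testing.assert_allclose(m1.eigenvalues, m2.eigenvalues, atol=1e-9)
        np.testing.assert_allclose(m1.eigenvectors, m2.eigenvectors, atol=1e-8)

    def test_butterfly_twist_recovery(self, toy_structure, toy_spec):
        motion = motion_for_variances(toy_structure, toy_spec, 9.0, 1.0,
                                      global_sigma=0.2, n_frames=2000, seed=3)
        traj, truth = generate_trajectory(toy_structure, motion, toy_spec)
        model = fit_pca(build_combined_ensemble([traj], toy_structure))
        assert abs(model.eigenvectors[:, 0] @ truth.hinge_mode) >= 0.95

    def test_too_few_frames(self, rng):
        ens = _ensemble_from_rows(rng.normal(size=(1, 9)).repeat(1, axis=0))
        with pytest.raises(ValueError):
            fit_pca(ens)


class TestProject:
    def test_mean_projects_to_zero(self, rng):
        ens = _ensemble_from_rows(rng.normal(size=(10, 9)))
        model = fit_pca(ens)
        series = project(model, model.mean, align=False)
        np.testing.assert_allclose(series.coordinates, 0.0, atol=1e-9)

    def test_ensemble_variance_equals_eigenvalues(self, rng):
        ens = _ensemble_from_rows(rng.normal(size=(40, 12)))
        model = fit_pca(ens)
        series = project(model, ens.matrix, align=False)
        np.testing.assert_allclose(series.coordinates.var(axis=0, ddof=1),
                                   model.eigenvalues, atol=1e-9)

    def test_unit_step_along_pc1(self, rng):
        ens = _ensemble_from_rows(rng.normal(size=(10, 9)))
        model = fit_pca(ens)
        a = 2.5
        series = project(model, model.mean + a * model.eigenvectors[:, 0],
                         align=False)
        assert series.coordinates[0, 0] == pytest.approx(a, abs=1e-9)
        np.testing.assert_allclose(series.coordinates[0, 1:], 0.0, atol=1e-9)

    def test_reconstruction_identity(self, rng):
        ens = _ensemble_from_rows(rng.normal(size=(12, 9)))
        model = fit_pca(ens)
        series = project(model, ens.matrix, align=False)
        recon = model.mean + series.coordinates @ model.eigenvectors.T
        np.testing.assert_allclose(recon, ens.matrix, atol=1e-8)

    def test_dimension_mismatch(self, rng):
        ens = _ensemble_from_rows(rng.normal(size=(10, 9)))
        model = fit_pca(ens)
        with pytest.raises(ValueError):
            project(model, np.zeros(12), align=False)

    def test_external_structure_projection(self, toy_structure, toy_spec):
        motion = MotionSpec(hinge_amplitude=5.0, n_frames=50, seed=2)
        traj, _ = generate_trajectory(toy_structure, motion, toy_spec)
        model = fit_pca(build_combined_ensemble([traj], toy_structure))
        series = project(model, toy_structure)
        assert series.coordinates.shape == (1, model.n_modes)


class TestVarianceExplained:
    def test_all_modes_is_one(self, rng):
        model = fit_pca(_ensemble_from_rows(rng.normal(size=(10, 9))))
        assert variance_explained(model, model.n_modes) == pytest.approx(1.0)

    def test_rank_one_single_mode(self, rng):
        ens, _, _ = _rank_one_ensemble(rng)
        model = fit_pca(ens)
        assert variance_explained(model, 1) == pytest.approx(1.0, abs=1e-9)

    def test_monotone_in_k(self, rng):
        model = fit_pca(_ensemble_from_rows(rng.normal(size=(25, 15))))
        fracs = [variance_explained(model, k) for k in range(1, model.n_modes + 1)]
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))

    def test_matches_analytic_fraction(self, toy_structure, toy_spec):
        motion = motion_for_variances(toy_structure, toy_spec, 9.0, 1.0,
                                      global_sigma=0.2, n_frames=2000, seed=3)
        traj, truth = generate_trajectory(toy_structure, motion, toy_spec)
        model = fit_pca(build_combined_ensemble([traj], toy_structure))
        analytic = (truth.hinge_variance + truth.twist_variance) / (
            truth.hinge_variance + truth.twist_variance + truth.noise_variance)
        assert variance_explained(model, 2) == pytest.approx(analytic, rel=0.05)


class TestExtremeStructures:
    def test_rank_one_endpoints(self, toy_structure):
        coords = toy_structure.coords
        lo = coords.copy()
        hi = coords.copy()
        lo[:, 0] -= 1.0
        hi[:, 0] += 1.0
        # displacement along x is a pure translation; plant an internal mode
        lo[:60, 1] -= 2.0
        hi[:60, 1] += 2.0
        traj = Trajectory(coords=np.stack([lo, coords, hi]),
                          atom_meta=toy_structure)
        ens = build_combined_ensemble([traj], toy_structure)
        model = fit_pca(ens)
        series = project(model, ens.matrix, align=False)
        mn, mx = extreme_structures(model, series, traj, pc=0)
        assert {int(series.coordinates[:, 0].argmin()),
                int(series.coordinates[:, 0].argmax())} == {0, 2}
        np.testing.assert_allclose(
            np.sort([series.coordinates[0, 0], series.coordinates[2, 0]]),
            np.sort(project(model, np.stack([mn.coords, mx.coords]).reshape(2, -1),
                            align=False).coordinates[:, 0]),
            atol=1e-4)  # extreme frames are re-aligned to the model mean,
        # the ensemble rows to the reference; the targets differ slightly

    def test_tie_broken_by_first_frame(self, toy_structure):
        coords = toy_structure.coords
        traj = Trajectory(coords=np.stack([coords] * 4),
                          atom_meta=toy_structure)
        ens = build_combined_ensemble([traj], toy_structure)
        # degenerate: all frames identical; both extremes must be frame 0
        model = fit_pca(_pad_rank(ens))
        series = project(model, ens.matrix, align=False)
        mn, mx = extreme_structures(model, series, traj, pc=0)
        np.testing.assert_allclose(mn.coords, traj.coords[0])
        np.testing.assert_allclose(mx.coords, traj.coords[0])

    def test_hinge_angle_difference_matches_amplitude(self, toy_structure,
                                                      toy_spec):
        amp = 8.0
        motion = MotionSpec(hinge_amplitude=amp, twist_amplitude=0.0,
                            n_frames=400, seed=6)
        traj, truth = generate_trajectory(toy_structure, motion, toy_spec)
        ens = build_combined_ensemble([traj], toy_structure)
        model = fit_pca(ens)
        series = project(model, ens.matrix, align=False)
        mn, mx = extreme_structures(model, series, traj, pc=0)
        angles = interdomain_angle_series(
            Trajectory(coords=np.stack([mn.coords, mx.coords]),
                       atom_meta=toy_structure),
            toy_spec, reference=toy_structure)
        assert abs(angles[1] - angles[0]) == pytest.approx(2 * amp, rel=0.10)

    def test_pc_out_of_range(self, rng, toy_structure):
        traj = Trajectory(coords=np.stack([toy_structure.coords] * 3)
                          + rng.normal(size=(3, 120, 3)),
                          atom_meta=toy_structure)
        ens = build_combined_ensemble([traj], toy_structure)
        model = fit_pca(ens)
        series = project(model, ens.matrix, align=False)
        with pytest.raises(ValueError):
            extreme_structures(model, series, traj, pc=10_000)


def _pad_rank(ens):
    # tiny jitter so fit_pca accepts a degenerate ensemble
    m = ens.matrix.copy()
    return EnsembleMatrix(matrix=m, labels=ens.labels, reference=ens.reference,
                          residue_numbers=ens.residue_numbers)


class TestMorph:
    def test_two_steps_are_endpoints(self, toy_structure):
        b = toy_structure.with_coords(toy_structure.coords + [1.0, 0.5, -2.0])
        path = morph(toy_structure, b, n_steps=2)
        assert path.n_frames == 2
        np.testing.assert_allclose(path.coords[0], toy_structure.coords,
                                   atol=1e-9)

    def test_midpoint_of_translation(self, toy_structure):
        shift = np.array([3.0, 0.0, 0.0])
        b = toy_structure.with_coords(toy_structure.coords + shift)
        path = morph(toy_structure, b, n_steps=3)
        # alignment removes the pure translation entirely
        np.testing.assert_allclose(path.coords[1], toy_structure.coords,
                                   atol=1e-9)

    def test_constant_step_rmsd(self, toy_structure, toy_spec):
        motion = MotionSpec(hinge_amplitude=10.0, n_frames=4, seed=1)
        traj, _ = generate_trajectory(toy_structure, motion, toy_spec)
        b = toy_structure.with_coords(traj.coords[1])
        path = morph(toy_structure, b, n_steps=8)
        steps = [
            np.sqrt(np.mean(np.sum((path.coords[i + 1] - path.coords[i]) ** 2,
                                   axis=1)))
            for i in range(path.n_frames - 1)
        ]
        np.testing.assert_allclose(steps, steps[0], atol=1e-6)

    def test_topology_mismatch(self, toy_structure):
        small = make_model([(i, "GLY", "CA", (i, 0, 0)) for i in range(1, 5)])
        with pytest.raises(ValueError):
            morph(toy_structure, small)


class TestModeOverlap:
    def test_self_overlap_identity(self, rng):
        model = fit_pca(_ensemble_from_rows(rng.normal(size=(20, 12))))
        ov = mode_overlap(model, model, k=3)
        np.testing.assert_allclose(ov.values, np.eye(3), atol=1e-8)

    def test_orthogonal_planted_modes(self, toy_structure, toy_spec):
        hinge_only = MotionSpec(hinge_amplitude=6.0, twist_amplitude=0.0,
                                n_frames=300, seed=1)
        twist_only = MotionSpec(hinge_amplitude=0.0, twist_amplitude=6.0,
                                n_frames=300, seed=2)
        t1, _ = generate_trajectory(toy_structure, hinge_only, toy_spec)
        t2, _ = generate_trajectory(toy_structure, twist_only, toy_spec)
        m1 = fit_pca(build_combined_ensemble([t1], toy_structure))
        m2 = fit_pca(build_combined_ensemble([t2], toy_structure))
        ov = mode_overlap(m1, m2, k=1)
        assert ov.values[0, 0] < 0.2

    def test_bounded_by_one(self, rng):
        a = fit_pca(_ensemble_from_rows(rng.normal(size=(15, 12))))
        b = fit_pca(_ensemble_from_rows(rng.normal(size=(18, 12))))
        ov = mode_overlap(a, b, k=4)
        assert np.all(ov.values <= 1.0 + 1e-12)
        assert np.all(ov.values >= 0.0)
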