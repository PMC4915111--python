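import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pssm.geometry import RigidTransform, rmsd, rotation_about_axis
from pssm.icp import (
    closest_points,
    cross_covariance,
    icp_register,
    kabsch_superpose,
    optimal_registration,
    q_matrix,
)
from pssm.simulate import make_synthetic_structure, random_rotation

R4 = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])


class TestCrossCovariance:
    def test_unit_basis_hand_value(self):
        basis = np.eye(3)
        expected = np.eye(3) / 3 - np.full((3, 3), 1.0 / 9.0)
        np.testing.assert_allclose(cross_covariance(basis, basis), expected,
                                   atol=1e-15)

    def test_single_point_is_zero(self):
        np.testing.assert_allclose(
            cross_covariance([[1.0, 2.0, 3.0]], [[4.0, 5.0, 6.0]]), np.zeros((3, 3))
        )

    def test_matches_direct_summation(self, rng):
        p = rng.normal(size=(40, 3))
        x = rng.normal(size=(40, 3))
        mu_p, mu_x = p.mean(0), x.mean(0)
        direct = sum(np.outer(pi - mu_p, xi - mu_x) for pi, xi in zip(p, x)) / 40
        np.testing.assert_allclose(cross_covariance(p, x), direct, atol=1e-12)

    def test_size_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            cross_covariance(rng.normal(size=(3, 3)), rng.normal(size=(4, 3)))


class TestQMatrix:
    def test_identity_sigma(self):
        np.testing.assert_allclose(q_matrix(np.eye(3)),
                                   np.diag([3.0, -1.0, -1.0, -1.0]))

    def test_symmetric_sigma_zero_delta(self, rng):
        s = rng.normal(size=(3, 3))
        sym = s + s.T
        Q = q_matrix(sym)
        np.testing.assert_allclose(Q[0, 1:], 0.0, atol=1e-15)

    def test_output_symmetric(self, rng):
        for _ in range(10):
            Q = q_matrix(rng.normal(size=(3, 3)))
            np.testing.assert_allclose(Q, Q.T, atol=1e-14)


class TestOptimalRegistration:
    def test_identical_sets_identity(self, rng):
        p = rng.normal(size=(12, 3))
        reg, d = optimal_registration(p, p)
        assert d == pytest.approx(0.0, abs=1e-20)
        assert reg.as_transform().is_identity(tol=1e-8)

    def test_recovers_90deg_z_rotation(self, rng):
        p = rng.normal(scale=5.0, size=(10, 3))
        x = p @ R4.T
        reg, d = optimal_registration(p, x)
        np.testing.assert_allclose(reg.as_transform().R, R4, atol=1e-10)
        assert d <= 1e-20 * 25.0

    def test_exact_for_any_rigid_motion(self):
        ps = make_synthetic_structure(50, seed=2)
        scale2 = float(np.max(np.sum(ps.coords**2, axis=1)))
        for seed in range(10):
            t = RigidTransform(random_rotation(seed).R, [3.0, -7.0, 1.0])
            reg, d = optimal_registration(ps.coords, t.apply(ps.coords))
            assert d <= 1e-18 * scale2
            np.testing.assert_allclose(reg.as_transform().R, t.R, atol=1e-8)

    def test_agrees_with_kabsch_on_noisy_pairs(self, rng):
        for _ in range(20):
            p = rng.normal(scale=8.0, size=(25, 3))
            x = p @ random_rotation(int(rng.integers(1 << 30))).R.T \
                + rng.normal(scale=0.5, size=(25, 3))
            reg, d = optimal_registration(p, x)
            _, kab_rmsd = kabsch_superpose(p, x)
            assert np.sqrt(d) == pytest.approx(kab_rmsd, abs=1e-10)

    def test_agrees_with_scipy_align_vectors(self, rng):
        # independent cross-check against an external Procrustes solver
        p = rng.normal(scale=5.0, size=(30, 3))
        x = p @ random_rotation(11).R.T + rng.normal(scale=0.3, size=(30, 3))
        reg, _ = optimal_registration(p, x)
        est, _ = Rotation.align_vectors(x - x.mean(0), p - p.mean(0))
        np.testing.assert_allclose(reg.as_transform().R, est.as_matrix(),
                                   atol=1e-8)


class TestClosestPoints:
    def test_single_nearest(self):
        Y = closest_points([[0.0, 0, 0]], [[1.0, 0, 0], [3.0, 0, 0]])
        np.testing.assert_allclose(Y, [[1.0, 0, 0]])

    def test_tie_breaks_to_lowest_index(self):
        Y = closest_points([[0.0, 0, 0]], [[1.0, 0, 0], [-1.0, 0, 0]])
        np.testing.assert_allclose(Y, [[1.0, 0, 0]])

    def test_empty_model_rejected(self):
        with pytest.raises(ValueError):
            closest_points([[0.0, 0, 0]], np.empty((0, 3)))

    @pytest.mark.parametrize("n, m", [(20, 20), (50, 100), (200, 200)])
    def test_matches_exhaustive_scan(self, n, m, rng):
        p = rng.normal(scale=5.0, size=(n, 3))
        x = rng.normal(scale=5.0, size=(m, 3))
        Y = closest_points(p, x)
        d2 = np.sum((p[:, None] - x[None]) ** 2, axis=-1)
        expected = x[np.argmin(d2, axis=1)]
        np.testing.assert_allclose(Y, expected)


class TestIcpRegister:
    def test_identical_sets_immediate_convergence(self, helix108):
        res = icp_register(helix108.coords, helix108.coords)
        assert res.converged
        assert res.iterations <= 2
        assert res.final_mse == pytest.approx(0.0, abs=1e-20)

    def test_small_rotation_converges_to_machine_precision(self, helix108):
        R = rotation_about_axis((0.3, 0.2, 0.9), 5.0)
        moved = helix108.coords @ R.T
        res = icp_register(helix108.coords, moved)
        assert res.converged
        assert res.final_mse < 1e-16

    def test_transform_is_cumulative_on_original_data(self, helix108):
        R = rotation_about_axis((0, 1, 0), 8.0)
        moved = helix108.coords @ R.T + np.array([1.0, 2.0, 3.0])
        res = icp_register(helix108.coords, moved)
        assert rmsd(res.transform.apply(helix108.coords), moved) < 1e-6

    @pytest.mark.parametrize("seed", range(10))
    def test_monotone_error_decrease_random_starts(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(scale=6.0, size=(60, 3))
        p = x @ random_rotation(seed + 500).R.T + rng.normal(scale=1.0, size=(60, 3))
        res = icp_register(p, x)
        errors = np.array(res.errors_by_iteration)
        assert np.all(np.diff(errors) <= 1e-12)

    def test_max_iter_reached_flags_not_converged(self, helix108):
        moved = helix108.coords @ random_rotation(9).R.T
        res = icp_register(helix108.coords, moved, tau=0.0, max_iter=3)
        assert not res.converged
        assert res.iterations == 3


class TestKabsch:
    def test_identity_on_identical_sets(self, rng):
        p = rng.normal(size=(10, 3))
        t, value = kabsch_superpose(p, p)
        assert value == pytest.approx(0.0, abs=1e-12)
        assert t.is_identity(tol=1e-8)

    def test_reflection_corrected(self, rng):
        p = rng.normal(size=(15, 3))
        x = p @ np.diag([1.0, 1.0, -1.0])  # mirrored target
        t, _ = kabsch_superpose(p, x)
        assert np.linalg.det(t.R) == pytest.approx(1.0, abs=1e-10)

    def test_residual_equals_recomputed_rmsd(self, rng):
        p = rng.normal(scale=5.0, size=(30, 3))
        x = p @ random_rotation(4).R.T + rng.normal(scale=0.4, size=(30, 3))
        t, value = kabsch_superpose(p, x)
        assert value == pytest.approx(rmsd(t.apply(p), x), abs=1e-12)
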