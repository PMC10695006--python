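"""Prior sampling, interpolation geometry, acquisition and optimisation."""

import numpy as np
import pytest

from cagevae.sampling import (
    AcquisitionConfig,
    acquisition,
    bayesian_optimize,
    latent_bounds,
    lerp,
    sample_prior,
    slerp,
)


class TestPrior:
    def test_moments_match_standard_normal(self):
        z = sample_prior(100_000, 4, rng_seed=0)
        se = 1.0 / np.sqrt(100_000)
        assert np.abs(z.mean(axis=0)).max() < 4 * se
        cov = np.cov(z.T)
        np.testing.assert_allclose(cov, np.eye(4), atol=0.02)

    def test_fixed_seed_reproducible(self):
        np.testing.assert_array_equal(sample_prior(10, 3, 5), sample_prior(10, 3, 5))

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError):
            sample_prior(0, 3, 0)


class TestLerp:
    def test_endpoints(self):
        z0, z1 = np.array([1.0, 0.0]), np.array([0.0, 2.0])
        path = lerp(z0, z1, 5)
        np.testing.assert_allclose(path.points[0], z0)
        np.testing.assert_allclose(path.points[-1], z1)

    def test_midpoint_of_antipodal_points_is_origin(self):
        z0 = np.array([3.0, -1.0, 2.0])
        path = lerp(z0, -z0, 3)
        np.testing.assert_allclose(path.points[1], np.zeros(3), atol=1e-14)

    def test_consecutive_distances_equal(self):
        rng = np.random.default_rng(0)
        z0, z1 = rng.standard_normal(8), rng.standard_normal(8)
        path = lerp(z0, z1, 7)
        gaps = np.linalg.norm(np.diff(path.points, axis=0), axis=1)
        np.testing.assert_allclose(gaps, np.linalg.norm(z1 - z0) / 6)

    def test_too_few_steps_rejected(self):
        with pytest.raises(ValueError):
            lerp(np.ones(2), np.zeros(2), 1)


class TestSlerp:
    def test_endpoints(self):
        rng = np.random.default_rng(1)
        z0, z1 = rng.standard_normal(6), rng.standard_normal(6)
        path = slerp(z0, z1, 9)
        np.testing.assert_allclose(path.points[0], z0, atol=1e-12)
        np.testing.assert_allclose(path.points[-1], z1, atol=1e-12)

    def test_orthogonal_unit_midpoint_closed_form(self):
        """Midpoint between orthogonal unit vectors is (z0+z1) * sqrt(2)/2."""
        z0 = np.array([1.0, 0.0])
        z1 = np.array([0.0, 1.0])
        path = slerp(z0, z1, 3)
        np.testing.assert_allclose(path.points[1], (z0 + z1) * np.sqrt(2) / 2,
                                   atol=1e-10)
        assert np.linalg.norm(path.points[1]) == pytest.approx(1.0, abs=1e-10)

    def test_norm_constant_on_equal_norm_sphere(self):
        rng = np.random.default_rng(2)
        z0 = rng.standard_normal(5)
        z1 = rng.standard_normal(5)
        z1 *= np.linalg.norm(z0) / np.linalg.norm(z1)
        path = slerp(z0, z1, 11)
        norms = np.linalg.norm(path.points, axis=1)
        np.testing.assert_allclose(norms, np.linalg.norm(z0), atol=1e-10)

    def test_parallel_endpoints_fall_back_to_lerp(self):
        z0 = np.array([1.0, 1.0])
        z1 = 3.0 * z0
        np.testing.assert_allclose(slerp(z0, z1, 5).points, lerp(z0, z1, 5).points,
                                   atol=1e-12)

    def test_zero_endpoint_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            slerp(np.zeros(3), np.ones(3), 4)


def _box(dim, lo=-3.0, hi=3.0):
    return np.tile([lo, hi], (dim, 1))


class TestAcquisition:
    def test_certain_target_at_origin_scores_zero(self):
        cfg = AcquisitionConfig(bounds=_box(2), target=0, omega=1.0)
        value = acquisition(np.zeros(2), lambda z: np.zeros(len(z)), cfg)
        assert value == pytest.approx(0.0, abs=1e-5)

    def test_half_probability_gives_ln2(self):
        cfg = AcquisitionConfig(bounds=_box(2), target=0, omega=0.0)
        value = acquisition(np.ones(2), lambda z: np.full(len(z), 0.5), cfg)
        assert value == pytest.approx(np.log(2), rel=1e-9)

    def test_regulariser_adds_half_square_norm(self):
        # p = 0.5, omega = 1, ||z||^2 = 2  ->  ln 2 + 1
        cfg = AcquisitionConfig(bounds=_box(2), target=0, omega=1.0)
        value = acquisition(np.array([1.0, 1.0]), lambda z: np.full(len(z), 0.5), cfg)
        assert value == pytest.approx(np.log(2) + 1.0, rel=1e-9)

    def test_linearity_in_omega(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal(4)
        pred = lambda zz: np.full(len(zz), 0.3)
        base = acquisition(z, pred, AcquisitionConfig(bounds=_box(4), omega=0.0))
        for omega in (0.1, 0.5, 2.0):
            cfg = AcquisitionConfig(bounds=_box(4), omega=omega)
            assert acquisition(z, pred, cfg) == pytest.approx(
                base + omega * 0.5 * float(z @ z), rel=1e-12)

    def test_probability_clamped_to_finite_value(self):
        cfg = AcquisitionConfig(bounds=_box(2), target=0, omega=0.0)
        value = acquisition(np.zeros(2), lambda z: np.ones(len(z)), cfg)
        assert np.isfinite(value)
        assert value == pytest.approx(-np.log(1e-6), rel=1e-6)

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            AcquisitionConfig(bounds=np.array([[0.0, 0.0], [-1.0, 1.0]]))


def _toy_predictor(z_star):
    """Collapse probability lowest at z_star: p = 1 - exp(-||z - z*||^2)."""
    def predict(z):
        z = np.atleast_2d(z)
        d2 = ((z - z_star) ** 2).sum(axis=1)
        return 1.0 - np.exp(-d2)
    return predict


class TestBayesianOptimize:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_recovers_known_optimum(self, seed):
        z_star = np.array([0.8, -1.2])
        cfg = AcquisitionConfig(bounds=_box(2), target=0, omega=0.0)
        points, values = bayesian_optimize(_toy_predictor(z_star), cfg,
                                           n_iterations=50, rng_seed=seed)
        assert np.linalg.norm(points[0] - z_star) < 0.1

    def test_all_points_inside_bounds(self):
        cfg = AcquisitionConfig(bounds=_box(3, -1.5, 2.0), omega=0.1)
        points, _ = bayesian_optimize(_toy_predictor(np.array([0.5, 0.5, 0.5])),
                                      cfg, n_iterations=25, rng_seed=0)
        assert (points >= -1.5 - 1e-12).all() and (points <= 2.0 + 1e-12).all()

    def test_large_omega_drives_best_toward_origin(self):
        z_star = np.array([2.0, 2.0])
        pred = _toy_predictor(z_star)
        best_norms = []
        for omega in (0.0, 50.0):
            cfg = AcquisitionConfig(bounds=_box(2), omega=omega)
            points, _ = bayesian_optimize(pred, cfg, n_iterations=40, rng_seed=1)
            best_norms.append(np.linalg.norm(points[0]))
        assert best_norms[1] < 0.3
        assert best_norms[1] < best_norms[0]

    def test_gradient_fallback_finds_optimum(self):
        z_star = np.array([0.5, -0.5])
        cfg = AcquisitionConfig(bounds=_box(2), omega=0.0)
        points, values = bayesian_optimize(_toy_predictor(z_star), cfg,
                                           n_iterations=100, rng_seed=0,
                                           method="gradient")
        assert np.linalg.norm(points[0] - z_star) < 0.05

    def test_results_ranked_by_value(self):
        cfg = AcquisitionConfig(bounds=_box(2), omega=0.0)
        _, values = bayesian_optimize(_toy_predictor(np.zeros(2)), cfg,
                                      n_iterations=20, rng_seed=2)
        assert (np.diff(values) >= 0).all()


class TestLatentBounds:
    def test_envelope(self):
        latents = np.array([[0.0, -1.0], [2.0, 3.0], [1.0, 0.0]])
        bounds = latent_bounds(latents)
        np.testing.assert_array_equal(bounds, [[0.0, 2.0], [-1.0, 3.0]])
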