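"""Latent-space generation strategies.

Random prior sampling probes the unconditional generative capacity;
repeated reconstruction of one cage probes the posterior neighbourhood;
lerp/slerp interpolation traverses between two known cages; and Bayesian
optimisation minimises an acquisition built from the jointly trained
shape-persistence predictor to steer generation toward persistent cages.

The acquisition is ``-log p(y = t | z) + omega * ||z||^2 / 2``: the
negative log-likelihood of the target label t (t = 0, shape-persistent)
plus an omega-weighted regulariser equal to the negative log standard-normal
density of z up to a constant, which keeps the search on the learnt
manifold. The search box is the per-dimension min/max envelope of the
training latents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import warnings

import numpy as np
from scipy.optimize import minimize
from scipy.stats import qmc
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern

__all__ = [
    "AcquisitionConfig",
    "InterpolationPath",
    "sample_prior",
    "lerp",
    "slerp",
    "acquisition",
    "bayesian_optimize",
    "latent_bounds",
]

_PROB_FLOOR = 1e-6


@dataclass(frozen=True)
class AcquisitionConfig:
    """Target label (0 = shape-persistent), exploration weight omega and the
    per-dimension search box."""

    bounds: np.ndarray  # (latent_dim, 2)
    target: int = 0
    omega: float = 0.1

    def __post_init__(self):
        bounds = np.asarray(self.bounds, dtype=np.float64)
        if bounds.ndim != 2 or bounds.shape[1] != 2:
            raise ValueError("bounds must have shape (latent_dim, 2)")
        if not np.isfinite(bounds).all():
            raise ValueError("bounds must be finite")
        if (bounds[:, 0] >= bounds[:, 1]).any():
            raise ValueError("degenerate bounds: min must be < max on every dimension")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.target not in (0, 1):
            raise ValueError("target must be a binary label")
        object.__setattr__(self, "bounds", bounds)


@dataclass(frozen=True)
class InterpolationPath:
    z0: np.ndarray
    z1: np.ndarray
    points: np.ndarray  # (steps, latent_dim)

    @property
    def steps(self) -> int:
        return self.points.shape[0]


def sample_prior(n: int, latent_dim: int, rng_seed: int) -> np.ndarray:
    """n i.i.d. draws from the standard-normal prior over the latent space."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return np.random.default_rng(rng_seed).standard_normal((n, latent_dim))


def lerp(z0: np.ndarray, z1: np.ndarray, steps: int) -> InterpolationPath:
    """Linear interpolation: points (1-t) z0 + t z1 at t = k/(steps-1)."""
    if steps < 2:
        raise ValueError("steps must be >= 2")
    z0 = np.asarray(z0, dtype=np.float64)
    z1 = np.asarray(z1, dtype=np.float64)
    t = np.linspace(0.0, 1.0, steps)[:, None]
    return InterpolationPath(z0, z1, (1.0 - t) * z0 + t * z1)


def slerp(z0: np.ndarray, z1: np.ndarray, steps: int,
          angle_tolerance: float = 1e-7) -> InterpolationPath:
    """Spherical linear interpolation along the great arc between z0 and z1.

    ``sin((1-t) W)/sin(W) * z0 + sin(t W)/sin(W) * z1`` with W the angle
    between the endpoints; falls back to lerp when the angle is below
    tolerance (parallel endpoints). Zero endpoints are rejected.
    """
    if steps < 2:
        raise ValueError("steps must be >= 2")
    z0 = np.asarray(z0, dtype=np.float64)
    z1 = np.asarray(z1, dtype=np.float64)
    n0, n1 = np.linalg.norm(z0), np.linalg.norm(z1)
    if n0 == 0.0 or n1 == 0.0:
        raise ValueError("slerp endpoints must be nonzero")
    cos_w = np.clip(z0 @ z1 / (n0 * n1), -1.0, 1.0)
    w = np.arccos(cos_w)
    if w < angle_tolerance:
        return lerp(z0, z1, steps)
    t = np.linspace(0.0, 1.0, steps)[:, None]
    points = (np.sin((1.0 - t) * w) * z0 + np.sin(t * w) * z1) / np.sin(w)
    return InterpolationPath(z0, z1, points)


def acquisition(z: np.ndarray, predict_collapse, config: AcquisitionConfig) -> float:
    """-log p(y = t | z) + omega ||z||^2 / 2, minimised over the box.

    `predict_collapse` maps latent vectors to the probability of collapse
    (label 1); probabilities are clamped away from {0, 1} so the value is
    finite everywhere.
    """
    z = np.asarray(z, dtype=np.float64)
    p_collapse = float(np.asarray(predict_collapse(z[None, :])).ravel()[0])
    p_target = p_collapse if config.target == 1 else 1.0 - p_collapse
    p_target = np.clip(p_target, _PROB_FLOOR, 1.0 - _PROB_FLOOR)
    return float(-np.log(p_target) + config.omega * 0.5 * float(z @ z))


def latent_bounds(latents: np.ndarray, pad: float = 0.0) -> np.ndarray:
    """Per-dimension [min, max] envelope of training latents."""
    latents = np.asarray(latents, dtype=np.float64)
    lo = latents.min(axis=0) - pad
    hi = latents.max(axis=0) + pad
    return np.stack([lo, hi], axis=1)


def _expected_improvement(mu, sigma, best):
    from scipy.stats import norm

    sigma = np.maximum(sigma, 1e-12)
    gap = best - mu
    u = gap / sigma
    return gap * norm.cdf(u) + sigma * norm.pdf(u)


def bayesian_optimize(
    predict_collapse,
    config: AcquisitionConfig,
    n_iterations: int = 50,
    rng_seed: int = 0,
    n_init: int = 10,
    n_candidates: int = 2048,
    method: str = "gp",
):
    """Minimise the acquisition inside the training-latent box.

    method="gp": a Gaussian-process surrogate (Matern 5/2) over observed
    acquisition values; each iteration evaluates the point maximising
    expected improvement over a quasi-random candidate set. method="gradient"
    is a multi-start L-BFGS-B fallback on the acquisition directly.

    Returns ``(points, values)`` with every evaluated point inside the box,
    jointly sorted by ascending acquisition value (best first).
    """
    rng = np.random.default_rng(rng_seed)
    bounds = config.bounds
    dim = bounds.shape[0]
    span = bounds[:, 1] - bounds[:, 0]

    def f(z):
        return acquisition(z, predict_collapse, config)

    if method == "gradient":
        pts, vals = [], []
        n_starts = max(2, n_iterations // 10)
        m = int(np.ceil(np.log2(n_starts)))
        starts = bounds[:, 0] + qmc.Sobol(dim, seed=rng_seed).random_base2(m)[:n_starts] * span
        for x0 in starts:
            res = minimize(f, x0, method="L-BFGS-B",
                           bounds=[tuple(b) for b in bounds],
                           options={"maxiter": n_iterations})
            pts.append(np.clip(res.x, bounds[:, 0], bounds[:, 1]))
            vals.append(float(res.fun))
        points = np.array(pts)
        values = np.array(vals)
    elif method == "gp":
        sampler = qmc.Sobol(dim, seed=rng_seed)
        m = int(np.ceil(np.log2(max(n_init, 2))))
        init = bounds[:, 0] + sampler.random_base2(m)[:n_init] * span
        points = list(init)
        values = [f(z) for z in points]
        kernel = ConstantKernel(1.0) * Matern(length_scale=np.full(dim, 1.0), nu=2.5)
        for _ in range(n_iterations - n_init):
            gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                          alpha=1e-6, random_state=rng_seed)
            with warnings.catch_warnings():
                # kernel length-scale fits on few points routinely stop at
                # the iteration cap; the surrogate is still usable
                warnings.simplefilter("ignore", category=ConvergenceWarning)
                gp.fit(np.array(points), np.array(values))
            best = min(values)

            def neg_ei(x):
                mu, sigma = gp.predict(x[None, :], return_std=True)
                return -float(_expected_improvement(mu, sigma, best)[0])

            cand = bounds[:, 0] + rng.random((n_candidates, dim)) * span
            mu, sigma = gp.predict(cand, return_std=True)
            pick = cand[np.argmax(_expected_improvement(mu, sigma, best))]
            # continuous polish of the EI winner (surrogate only; one true
            # acquisition evaluation per iteration)
            res = minimize(neg_ei, pick, method="L-BFGS-B",
                           bounds=[tuple(b) for b in bounds],
                           options={"maxiter": 20})
            nxt = np.clip(res.x, bounds[:, 0], bounds[:, 1])
            points.append(nxt)
            values.append(f(nxt))
        points = np.array(points)
        values = np.array(values)
    else:
        raise ValueError(f"unknown method {method!r}")

    order = np.argsort(values)
    return points[order], values[order]
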