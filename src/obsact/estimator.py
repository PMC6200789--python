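"""Bayes-Least-Squares (BLS) inference stage of the observer-actor model.

The observer receives a noisy pre-inference value ``x_pre`` (the noisy
measurement under early inference, or the noisy transformed value under
late inference) and forms the estimate that minimises expected squared
error of the eventual *production*, accounting for post-inference noise:

    f_BLS(x_pre) = argmin_t  E_{t_c | x_pre} [ (t_p - t_c)^2 ]  with  t_p ~ p(. | t)

With a uniform prior pi(t_c) on [a, b] and Gaussian measurement likelihood
p(x_pre | t_c), the posterior is proportional to likelihood x prior, and
the solution has a closed form:

* additive production noise:   f_BLS = E[t_c | x_pre]                (posterior mean)
* scalar production noise:     f_BLS = E[t_c | x_pre] / (1 + w_post^2)

The denominator shifts estimates toward smaller magnitudes, where scalar
production noise is cheaper.  :func:`bls_numeric` minimises the expected
loss by brute force on a dense candidate grid and serves as the
independent oracle for :func:`bls_closed_form`.

All marginalisation uses composite Simpson quadrature on an odd-length
node grid (:class:`EstimatorGrid`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .noise import NoiseModel, noise_logpdf
from .priors import DISCRETE, PriorSpec

__all__ = [
    "EstimatorGrid",
    "Posterior",
    "DegeneratePosteriorError",
    "simpson_weights",
    "posterior",
    "bls_closed_form",
    "bls_numeric",
    "bls_estimate",
]

# Densities below exp(_LOG_FLOOR) underflow float64; a posterior whose best
# node is that unlikely is numerically zero everywhere in direct arithmetic.
_LOG_FLOOR = np.log(1e-300)


@dataclass(frozen=True)
class EstimatorGrid:
    """Quadrature settings: `n_nodes` Simpson nodes (odd, >= 51) over the prior
    support, and `span_sd` half-width (in local noise SDs) for marginalising
    over the unobserved pre-inference variable."""

    n_nodes: int = 201
    span_sd: float = 4.0

    def __post_init__(self) -> None:
        n = int(self.n_nodes)
        if n < 51 or n % 2 == 0:
            raise ValueError("n_nodes must be an odd integer >= 51")
        if self.span_sd <= 0:
            raise ValueError("span_sd must be positive")


class DegeneratePosteriorError(ValueError):
    """Raised when the posterior is numerically zero over the whole support."""


def simpson_weights(n: int, h: float) -> np.ndarray:
    """Composite Simpson quadrature weights for `n` (odd) evenly spaced nodes."""
    if n < 3 or n % 2 == 0:
        raise ValueError("Simpson's rule needs an odd number of nodes >= 3")
    w = np.ones(n)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    return w * (h / 3.0)


@dataclass(frozen=True)
class Posterior:
    """Normalised posterior over candidate correct values.

    For a continuous prior, `density` integrates (Simpson) to 1 using
    `weights`; for a discrete prior, `density` is a pmf and `weights` are 1.
    """

    nodes: np.ndarray
    density: np.ndarray
    weights: np.ndarray
    degenerate: bool = False

    def mean(self) -> float:
        return float(np.sum(self.weights * self.density * self.nodes))

    def integral(self) -> float:
        return float(np.sum(self.weights * self.density))

    def expect(self, values: np.ndarray) -> float:
        return float(np.sum(self.weights * self.density * np.asarray(values)))


def posterior(prior: PriorSpec, noise_pre: NoiseModel, x_pre: float, grid: EstimatorGrid | None = None) -> Posterior:
    """Posterior over the correct value given a pre-inference observation.

    The posterior weight at node ``t`` is proportional to
    ``p(x_pre | t) * pi(t)``; with a uniform prior the prior factor is
    constant and cancels in the normalisation.  Numerically the log
    likelihood is max-stabilised, so a result is returned even when the
    observation is far from the support, with ``degenerate=True`` flagging
    that the unstabilised density underflows everywhere.
    """
    if grid is None:
        grid = EstimatorGrid()
    if not np.isfinite(x_pre):
        raise ValueError("x_pre must be finite")
    if noise_pre.param == 0:
        raise ValueError("posterior with zero pre-inference noise is a delta function")

    if prior.form == DISCRETE:
        nodes = prior.support()
        weights = np.ones_like(nodes)
    else:
        nodes = np.linspace(prior.lower, prior.upper, grid.n_nodes)
        weights = simpson_weights(grid.n_nodes, nodes[1] - nodes[0])

    loglik = noise_logpdf(noise_pre, x_pre, nodes)
    peak = float(np.max(loglik))
    degenerate = peak < _LOG_FLOOR
    lik = np.exp(loglik - peak)
    norm = float(np.sum(weights * lik))
    return Posterior(nodes=nodes, density=lik / norm, weights=weights, degenerate=degenerate)


def _apply_post_correction(mean, noise_post: NoiseModel):
    if noise_post.kind == "scalar":
        return mean / (1.0 + noise_post.param**2)
    return mean


def bls_closed_form(
    x_pre: float,
    prior: PriorSpec,
    noise_pre: NoiseModel,
    noise_post: NoiseModel,
    grid: EstimatorGrid | None = None,
) -> float:
    """Closed-form BLS estimate (posterior mean, divided by ``1 + w_post^2``
    when production noise is scalar).  Raises
    :class:`DegeneratePosteriorError` for observations numerically outside
    the support."""
    post = posterior(prior, noise_pre, x_pre, grid)
    if post.degenerate:
        raise DegeneratePosteriorError(
            f"posterior numerically zero everywhere for x_pre={x_pre!r} on "
            f"[{prior.lower}, {prior.upper}]"
        )
    return float(_apply_post_correction(post.mean(), noise_post))


def bls_numeric(
    x_pre: float,
    prior: PriorSpec,
    noise_pre: NoiseModel,
    noise_post: NoiseModel,
    grid: EstimatorGrid | None = None,
    n_candidates: int = 2001,
) -> float:
    """Brute-force minimiser of the expected squared production error.

    The inner integral over the produced value is analytic,
    ``E[(t_p - t_c)^2 | t] = (t - t_c)^2 + SD_post(t)^2``; the outer
    expectation over the posterior is evaluated on the quadrature grid for
    every candidate ``t`` on a dense grid, followed by one parabolic
    refinement step around the grid argmin.  Serves as the independent
    oracle for :func:`bls_closed_form`.
    """
    post = posterior(prior, noise_pre, x_pre, grid)
    if post.degenerate:
        raise DegeneratePosteriorError(
            f"posterior numerically zero everywhere for x_pre={x_pre!r} on "
            f"[{prior.lower}, {prior.upper}]"
        )
    lo, hi = prior.lower, prior.upper
    if noise_post.kind == "scalar":
        lo = lo / (1.0 + noise_post.param**2)
    cand = np.linspace(lo, hi, int(n_candidates))
    sd_post = noise_post.sd(cand) if noise_post.param > 0 else np.zeros_like(cand)
    # (candidates, nodes) squared-error matrix, posterior-averaged per candidate
    sq = (cand[:, None] - post.nodes[None, :]) ** 2
    loss = sq @ (post.weights * post.density) + sd_post**2
    k = int(np.argmin(loss))
    if 0 < k < len(cand) - 1:
        denom = loss[k + 1] - 2.0 * loss[k] + loss[k - 1]
        if denom > 0:
            h = cand[1] - cand[0]
            return float(cand[k] - 0.5 * h * (loss[k + 1] - loss[k - 1]) / denom)
    return float(cand[k])


def bls_estimate(
    x_pre,
    prior: PriorSpec,
    noise_pre: NoiseModel,
    noise_post: NoiseModel,
    grid: EstimatorGrid | None = None,
    chunk: int = 50_000,
):
    """Vectorised closed-form BLS estimate for an array of observations.

    Used by the trial simulator and the likelihood; identical to
    :func:`bls_closed_form` per element.  A zero pre-inference noise
    parameter makes the posterior a point mass at the observation (clipped
    to the support).
    """
    if grid is None:
        grid = EstimatorGrid()
    x = np.atleast_1d(np.asarray(x_pre, dtype=float))

    if noise_pre.param == 0:
        mean = np.clip(x, prior.lower, prior.upper)
        out = _apply_post_correction(mean, noise_post)
        return out if np.ndim(x_pre) else float(out[0])

    if prior.form == DISCRETE:
        nodes = prior.support()
        weights = np.ones_like(nodes)
    else:
        nodes = np.linspace(prior.lower, prior.upper, grid.n_nodes)
        weights = simpson_weights(grid.n_nodes, nodes[1] - nodes[0])

    mean = np.empty_like(x)
    for start in range(0, len(x), chunk):
        xs = x[start : start + chunk, None]
        loglik = noise_logpdf(noise_pre, xs, nodes[None, :])
        loglik -= loglik.max(axis=1, keepdims=True)
        lik = np.exp(loglik) * weights
        mean[start : start + chunk] = (lik @ nodes) / lik.sum(axis=1)
    out = _apply_post_correction(mean, noise_post)
    return out if np.ndim(x_pre) else float(out[0])
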