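"""Trial simulation under the no-inference, early-inference, and
late-inference observer-actor strategies.

The chain per trial, for a sample ``s`` drawn from the task prior and a
context transform ``T``:

* **none**:   x = noisy(T(s));            p = noisy(x)
* **early**:  x = noisy(s);  s_hat = f_BLS(x) with the prior over samples;
              p = noisy(T(s_hat))
* **late**:   x = noisy(T(s));  t_i = f_BLS(x) with the prior over
              transformed values;  p = noisy(t_i)

Under late inference, scalar pre-inference noise scales with the
*transformed* value (the noisy quantity is the transformed one, and Weber
noise scales with its own mean).  Lapse trials replace the production with
a uniform draw over a broad range; a constant per-subject offset is added
to every production.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimator import EstimatorGrid, bls_estimate
from .noise import NoiseModel
from .priors import CONTINUOUS, DISCRETE, PriorSpec, Transform

__all__ = [
    "ObserverParams",
    "TRIAL_COLUMNS",
    "inference_prior_for",
    "simulate_trials",
    "compare_strategies",
]

STRATEGIES = ("none", "early", "late")

#: Canonical trial-table column order (also the CSV schema, see :mod:`obsact.io`).
TRIAL_COLUMNS = [
    "subject_id",
    "session",
    "block",
    "trial",
    "context",
    "sample",
    "correct",
    "produced",
    "units",
    "excluded_reason",
]


@dataclass(frozen=True)
class ObserverParams:
    """Observer strategy plus its two noise stages.

    ``strategy="none"`` produces the noisy transformed measurement with no
    inference stage.  ``lapse_rate`` is the probability that a production is
    replaced by a uniform guess; ``offset`` is a constant added to every
    production (a subject's overall tendency to respond long/short).
    """

    strategy: str
    noise_pre: NoiseModel
    noise_post: NoiseModel
    lapse_rate: float = 0.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; expected one of {STRATEGIES}")
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ValueError("lapse_rate must be in [0, 1]")
        if not np.isfinite(self.offset):
            raise ValueError("offset must be finite")


def inference_prior_for(
    sample_prior: PriorSpec, transform: Transform, strategy: str, form: str = CONTINUOUS
) -> PriorSpec:
    """The observer's internal prior at the inference stage.

    Early inference integrates over the sample prior; late (and none)
    inference over the prior of transformed values.  The internal prior is
    continuous uniform over the support range by default (matching
    Simpson-rule integration over the posterior); pass
    ``form="discrete_uniform"`` for the discrete variant.
    """
    base = sample_prior if strategy == "early" else sample_prior.transformed(transform)
    if form == CONTINUOUS:
        return base.as_continuous()
    if form == DISCRETE:
        if base.form != DISCRETE:
            raise ValueError("discrete inference prior requires a discrete sample prior")
        return base
    raise ValueError(f"unknown prior form {form!r}")


def _draw_samples(prior: PriorSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    if prior.form == DISCRETE:
        # uniform with replacement: per-sample trial counts are not balanced
        return rng.choice(prior.support(), size=n)
    return rng.uniform(prior.lower, prior.upper, size=n)


def _noisy(noise: NoiseModel, center: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return center + noise.sd(center) * rng.standard_normal(center.shape)


def default_lapse_range(transform: Transform, sample_prior: PriorSpec) -> tuple[float, float]:
    """Broad uniform production range for lapse trials:
    [0.5 x min correct, 1.5 x max correct]."""
    lo, hi = transform.bounds(sample_prior.lower, sample_prior.upper)
    a, b = 0.5 * lo, 1.5 * hi
    return (a, b) if a < b else (b, a)


def simulate_trials(
    params: ObserverParams,
    transform: Transform,
    sample_prior: PriorSpec,
    n: int,
    seed,
    inference_prior: PriorSpec | None = None,
    grid: EstimatorGrid | None = None,
    lapse_range: tuple[float, float] | None = None,
    subject_id: str = "sim",
    context: str = "sim",
    units: str = "",
) -> pd.DataFrame:
    """Simulate `n` trials of one observer in one context.

    Returns a trial table (one row per trial) with columns
    :data:`TRIAL_COLUMNS`.  Deterministic given `seed`.
    """
    if n < 1:
        raise ValueError("n must be a positive integer")
    if grid is None:
        grid = EstimatorGrid()
    if inference_prior is None:
        inference_prior = inference_prior_for(sample_prior, transform, params.strategy)
    else:
        expect = sample_prior if params.strategy == "early" else sample_prior.transformed(transform)
        if not (inference_prior.lower <= expect.lower + 1e-9 and inference_prior.upper >= expect.upper - 1e-9):
            raise ValueError(
                "inference_prior does not cover the support of the variable at the "
                f"inference stage ([{expect.lower}, {expect.upper}])"
            )
    rng = np.random.default_rng(seed)

    s = _draw_samples(sample_prior, int(n), rng)
    correct = transform.apply(s)

    if params.strategy == "early":
        x = _noisy(params.noise_pre, s, rng)
        s_hat = bls_estimate(x, inference_prior, params.noise_pre, params.noise_post, grid)
        center = transform.apply(s_hat)
    elif params.strategy == "late":
        x = _noisy(params.noise_pre, correct, rng)
        center = bls_estimate(x, inference_prior, params.noise_pre, params.noise_post, grid)
    else:  # no inference
        center = _noisy(params.noise_pre, correct, rng)
    produced = _noisy(params.noise_post, center, rng)

    if params.lapse_rate > 0:
        lo, hi = lapse_range if lapse_range is not None else default_lapse_range(transform, sample_prior)
        guesses = rng.uniform(lo, hi, size=int(n))
        mask = rng.random(int(n)) < params.lapse_rate
        produced = np.where(mask, guesses, produced)
    produced = produced + params.offset

    out = pd.DataFrame(
        {
            "subject_id": subject_id,
            "session": 1,
            "block": 1,
            "trial": np.arange(1, int(n) + 1),
            "context": context,
            "sample": s,
            "correct": correct,
            "produced": produced,
            "units": units,
            "excluded_reason": pd.Series([pd.NA] * int(n), dtype="string"),
        },
        columns=TRIAL_COLUMNS,
    )
    for col in ("subject_id", "context", "units"):
        out[col] = out[col].astype("string")
    return out


def compare_strategies(
    noise_pre: NoiseModel,
    noise_post: NoiseModel,
    mtn_levels,
    transform: Transform,
    sample_prior: PriorSpec,
    n: int,
    seed: int,
    grid: EstimatorGrid | None = None,
) -> pd.DataFrame:
    """Simulate the early/late strategy geometry across mental-transformation
    noise (MTN) levels.

    The same MTN magnitude is injected for both strategies, folded in
    quadrature into the post-inference noise for the early observer (MTN
    happens after its inference) and into the pre-inference noise for the
    late observer (MTN happens before).  Returns one row per
    (strategy, MTN level) with BIAS, sqrt(VAR), and RMSE, reproducing the
    quarter-circle geometry: late inference trades extra BIAS for a smaller
    RMSE, early inference pays for MTN in variability.
    """
    from .stats import summarize  # local import to avoid a cycle

    rows = []
    for si, strategy in enumerate(("early", "late")):
        for li, m in enumerate(mtn_levels):
            if strategy == "early":
                params = ObserverParams(strategy, noise_pre, noise_post.combined(float(m)))
            else:
                params = ObserverParams(strategy, noise_pre.combined(float(m)), noise_post)
            table = simulate_trials(
                params, transform, sample_prior, n, seed=[seed, si, li], grid=grid, context="identity"
            )
            stats = summarize(table)
            rows.append(
                {
                    "strategy": strategy,
                    "mtn": float(m),
                    "bias": stats.bias,
                    "sqrt_var": stats.sqrt_var,
                    "rmse": stats.rmse,
                }
            )
    return pd.DataFrame(rows)
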