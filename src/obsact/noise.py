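"""Gaussian noise models for the observer-actor chain.

Two variability regimes occur in timing, length, and reaching psychophysics:

* **scalar** (Weber) noise — the standard deviation grows proportionally with
  the magnitude of the represented quantity, ``SD = w * center``, with ``w``
  a dimensionless Weber fraction.  This is the classic signature of interval
  timing and magnitude estimation.
* **additive** noise — a constant standard deviation ``sigma`` in stimulus
  units, independent of the represented magnitude, appropriate for e.g.
  reach direction.

Both stages of the observer-actor model (pre-inference and post-inference)
are parameterised by one :class:`NoiseModel` each.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NoiseModel", "sample_noisy", "noise_density", "noise_logpdf"]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)

SCALAR = "scalar"
ADDITIVE = "additive"
_KINDS = (SCALAR, ADDITIVE)


@dataclass(frozen=True)
class NoiseModel:
    """A Gaussian noise source, either scalar (Weber) or additive.

    Parameters
    ----------
    kind : {"scalar", "additive"}
        Scalar noise has ``SD = param * center`` (Weber scaling); additive
        noise has ``SD = param`` regardless of center.
    param : float
        Weber fraction (dimensionless) for scalar noise, standard deviation
        in stimulus units for additive noise.  Must be non-negative.
    """

    kind: str
    param: float

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown noise kind {self.kind!r}; expected one of {_KINDS}")
        if not np.isfinite(self.param) or self.param < 0:
            raise ValueError(f"noise param must be a finite non-negative real, got {self.param}")

    def sd(self, center):
        """Standard deviation of the sampling distribution centered on `center`.

        Scalar noise is undefined for non-positive centers (the Weber SD
        would vanish or flip sign), so those raise a ``ValueError``.
        """
        c = np.asarray(center, dtype=float)
        if self.kind == SCALAR:
            if np.any(c <= 0):
                raise ValueError("scalar (Weber) noise requires a strictly positive center")
            return self.param * c
        return np.full(c.shape, float(self.param))

    def with_param(self, param: float) -> "NoiseModel":
        return NoiseModel(self.kind, param)

    def combined(self, extra: float) -> "NoiseModel":
        """Fold an extra independent noise source of the same kind in quadrature."""
        if extra < 0:
            raise ValueError("extra noise magnitude must be non-negative")
        return NoiseModel(self.kind, float(np.hypot(self.param, extra)))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_noisy(noise: NoiseModel, center, seed):
    """Draw from the noise model centered on `center`.

    `center` may be a scalar or array; `seed` may be an int, a seed sequence,
    or an already-constructed ``numpy.random.Generator``.  A zero noise
    parameter returns `center` exactly.  Deterministic given the seed.
    """
    rng = _as_rng(seed)
    c = np.asarray(center, dtype=float)
    sd = noise.sd(c)
    draw = c + sd * rng.standard_normal(c.shape)
    if np.ndim(center) == 0:
        return float(draw)
    return draw


def noise_logpdf(noise: NoiseModel, value, center):
    """Log Gaussian density of `value` under the noise model centered on `center`."""
    if noise.param == 0:
        raise ValueError("density of a zero-noise model is degenerate (delta function)")
    v = np.asarray(value, dtype=float)
    c = np.asarray(center, dtype=float)
    sd = noise.sd(c)
    z = (v - c) / sd
    return -0.5 * z * z - np.log(sd) - _LOG_SQRT_2PI


def noise_density(noise: NoiseModel, value, center):
    """Gaussian density of `value`; integrates to 1 over the real line."""
    out = np.exp(noise_logpdf(noise, value, center))
    if np.ndim(value) == 0 and np.ndim(center) == 0:
        return float(out)
    return out
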