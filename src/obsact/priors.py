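"""Stimulus priors and context transformations.

A :class:`PriorSpec` describes either the discrete uniform distribution
samples are drawn from (e.g. 11 intervals evenly spaced on [600, 1000] ms)
or the continuous uniform belief the observer integrates over.  A
:class:`Transform` maps a sample to the correct response for a context:
a multiplicative gain (time/length tasks) or an additive offset
(visuomotor rotation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["PriorSpec", "Transform"]

CONTINUOUS = "continuous_uniform"
DISCRETE = "discrete_uniform"


@dataclass(frozen=True)
class PriorSpec:
    """Uniform prior over an interval, continuous or discrete.

    Discrete form: `n_points` evenly spaced values from `lower` to `upper`
    inclusive.
    """

    lower: float
    upper: float
    form: str = CONTINUOUS
    n_points: Optional[int] = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
            raise ValueError("prior bounds must be finite")
        if not self.lower < self.upper:
            raise ValueError(f"prior requires lower < upper, got [{self.lower}, {self.upper}]")
        if self.form not in (CONTINUOUS, DISCRETE):
            raise ValueError(f"unknown prior form {self.form!r}")
        if self.form == DISCRETE:
            if self.n_points is None or int(self.n_points) < 2:
                raise ValueError("discrete prior needs n_points >= 2")
        elif self.n_points is not None:
            raise ValueError("n_points only applies to the discrete form")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def support(self) -> np.ndarray:
        """The discrete support; error for the continuous form."""
        if self.form != DISCRETE:
            raise ValueError("continuous prior has no enumerable support")
        return np.linspace(self.lower, self.upper, int(self.n_points))

    def as_continuous(self) -> "PriorSpec":
        return PriorSpec(self.lower, self.upper, CONTINUOUS)

    def transformed(self, transform: "Transform") -> "PriorSpec":
        """Prior over the transformed variable (bounds mapped through the transform)."""
        lo, hi = transform.bounds(self.lower, self.upper)
        return PriorSpec(lo, hi, self.form, self.n_points)


@dataclass(frozen=True)
class Transform:
    """Context remapping: ``gain`` (correct = value * sample, value > 0) or
    ``offset`` (correct = sample + value)."""

    kind: str
    value: float

    def __post_init__(self) -> None:
        if self.kind not in ("gain", "offset"):
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if not np.isfinite(self.value):
            raise ValueError("transform value must be finite")
        if self.kind == "gain" and self.value <= 0:
            raise ValueError("gain must be strictly positive")

    def apply(self, x):
        x = np.asarray(x, dtype=float)
        out = self.value * x if self.kind == "gain" else x + self.value
        return float(out) if out.ndim == 0 else out

    __call__ = apply

    def bounds(self, lower: float, upper: float) -> tuple[float, float]:
        a, b = self.apply(lower), self.apply(upper)
        return (a, b) if a <= b else (b, a)
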