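"""The fitness curve and fitness aggregation over time.

Fitness declines with the distance ``d = |phi - E|`` between an agent's
phenotype and the environmental optimum:

    f(d) = 1 / (1 + (d / scale)^(2*gamma))

The curve is Gaussian-like but cheaper to evaluate: maximum 1 at ``d = 0``,
exactly 1/2 at ``d = scale``, and strictly positive everywhere so geometric
means are always defined.  The sharpness ``gamma`` controls how abruptly
fitness collapses once ``d`` crosses the distance scale: for ``d < scale``
larger gamma raises fitness, for ``d > scale`` it crushes it.  That threshold
behavior — mild penalties inside the scale, catastrophic ones outside — is
what lets a rapid environmental reversal selectively eliminate close trackers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DualsimError, InvalidSpecError


@dataclass(frozen=True)
class FitnessParams:
    """Sharpness ``gamma`` (> 0, any positive real) and the distance at which
    fitness equals 1/2 (``distance_scale``, default 1)."""

    gamma: float
    distance_scale: float = 1.0

    def __post_init__(self) -> None:
        if not (self.gamma > 0):
            raise InvalidSpecError("gamma must be > 0")
        if not (self.distance_scale > 0):
            raise InvalidSpecError("distance_scale must be > 0")


def fitness_value(phi, env_value, params: FitnessParams):
    """Fitness of phenotype ``phi`` against optimum ``env_value``; symmetric
    in its two arguments, equal to 1 iff they coincide, strictly decreasing
    in their distance.  Accepts scalars or arrays (broadcasting)."""
    phi = np.asarray(phi, dtype=float)
    env_value = np.asarray(env_value, dtype=float)
    if not (np.all(np.isfinite(phi)) and np.all(np.isfinite(env_value))):
        raise DualsimError("non-finite phenotype or environment value")
    d = np.abs(phi - env_value) / params.distance_scale
    out = 1.0 / (1.0 + d ** (2.0 * params.gamma))
    if out.ndim == 0:
        return float(out)
    return out


def arithmetic_mean_fitness(fitnesses) -> float:
    """Ordinary mean of a non-empty fitness sequence."""
    f = np.asarray(fitnesses, dtype=float)
    if f.size == 0:
        raise DualsimError("empty fitness sequence")
    return float(f.mean())


def geometric_mean_fitness(fitnesses) -> float:
    """``exp(mean(log f))``; never exceeds the arithmetic mean, with equality
    iff all entries are equal.  Selection in fluctuating environments
    maximizes this quantity, which penalizes variance in fitness."""
    f = np.asarray(fitnesses, dtype=float)
    if f.size == 0:
        raise DualsimError("empty fitness sequence")
    if np.any(f <= 0):
        raise DualsimError("geometric mean requires strictly positive fitnesses")
    return float(np.exp(np.mean(np.log(f))))
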