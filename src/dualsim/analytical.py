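"""Deterministic capped phenotype tracking of a cyclical environment.

A tracker moves its phenotype toward the current optimum by at most
``max_step`` (the accuracy trait ``x``) per timestep.  On a sawtooth
environment the trajectory settles into a steady cycle with the environment's
period; the per-cycle mean fitness (geometric by default) defines a fitness
landscape over ``x``.  Two results follow numerically:

* a critical sharpness ``gamma*`` above which a slower tracker out-scores a
  faster one (the faster one hugs the rise and is stranded by the crash), and
* an interior local maximum of the landscape at intermediate ``x``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, NamedTuple

import numpy as np
from numba import njit
from scipy.optimize import bisect

from .environments import EnvironmentSeries
from .errors import BracketError, InvalidSpecError, NoConvergenceError
from .fitness import (
    FitnessParams,
    arithmetic_mean_fitness,
    fitness_value,
    geometric_mean_fitness,
)

MeanKind = Literal["arithmetic", "geometric"]

#: Absolute tolerance comparing successive cycle windows, and the cycle cap.
STEADY_TOL = 1e-12
MAX_CYCLES = 10_000


@dataclass(frozen=True)
class TrackerSpec:
    """A deterministic tracker: maximum phenotype change per timestep
    (``max_step``, the accuracy ``x``) and initial phenotype ``phi0``."""

    max_step: float
    phi0: float = 0.0

    def __post_init__(self) -> None:
        if self.max_step < 0:
            raise InvalidSpecError("max_step must be >= 0")


@dataclass(frozen=True)
class Trajectory:
    """Phenotype and fitness per timestep; ``period`` is filled by
    :func:`steady_cycle` when requested."""

    phi: np.ndarray
    fitness: np.ndarray
    period: int | None = None


class SteadyCycle(NamedTuple):
    start: int
    period: int
    degenerate: bool  # True for a constant (period-1) steady state


class XLandscape(NamedTuple):
    x: np.ndarray
    fitness: np.ndarray


def track_phenotype(env: EnvironmentSeries, tracker: TrackerSpec,
                    params: FitnessParams,
                    order: Literal["env_first", "move_first"] = "env_first",
                    ) -> Trajectory:
    """Iterate the capped tracking map over the whole series.

    With the default ``env_first`` order the environment takes its value
    ``E[t]`` first, the tracker then moves toward it by
    ``min(max_step, |E[t] - phi[t-1]|)``, and fitness is evaluated at the
    post-move phenotype against ``E[t]``.  ``phi[0] = phi0`` (no move at
    ``t = 0``).  When the target is within reach the tracker lands on it
    exactly; when already at the optimum it stays put.
    """
    E = env.values
    n = E.size
    phi = np.empty(n)
    phi[0] = tracker.phi0
    for t in range(1, n):
        target = E[t] if order == "env_first" else E[t - 1]
        d = target - phi[t - 1]
        if abs(d) <= tracker.max_step:
            phi[t] = target
        else:
            phi[t] = phi[t - 1] + np.sign(d) * tracker.max_step
    fit = fitness_value(phi, E, params)
    return Trajectory(phi=phi, fitness=np.atleast_1d(fit))


def _divisors(n: int) -> list[int]:
    return [d for d in range(1, n + 1) if n % d == 0]


def _is_periodic(x: np.ndarray, p: int, tol: float) -> bool:
    if x.size < 2 * p:
        return False
    return bool(np.max(np.abs(x[p:] - x[:-p])) <= tol)


def steady_cycle(traj: Trajectory, env_period: int, tol: float = STEADY_TOL,
                 ) -> SteadyCycle:
    """First index after which ``phi`` repeats with a period dividing (or a
    multiple of) ``env_period``, plus the minimal such period.

    A constant steady state is reported as period 1 with the degenerate flag
    set.  Raises :class:`NoConvergenceError` if no periodicity is found.
    """
    phi = traj.phi
    n = phi.size
    if n < 3 * env_period:
        raise InvalidSpecError("trajectory must span at least 3 environment periods")
    candidates = [env_period] + [
        m * env_period for m in range(2, n // (2 * env_period) + 1)
    ]
    for p in candidates:
        for s in range(0, n - 2 * p + 1):
            if _is_periodic(phi[s:], p, tol):
                minimal = next(d for d in _divisors(p) if _is_periodic(phi[s:], d, tol))
                return SteadyCycle(start=s, period=minimal, degenerate=minimal == 1)
    raise NoConvergenceError("no steady cycle detected within the trajectory")


@njit(cache=False)
def _iterate_cycle(cycle, max_step, phi0, tol, max_cycles):  # pragma: no cover
    """Iterate the tracking map over repeated cycles until two successive
    cycle-length phenotype windows agree within ``tol``.  Returns the steady
    window, or an empty array on non-convergence."""
    p = cycle.shape[0]
    prev = np.empty(p)
    cur = np.empty(p)
    phi = phi0
    for it in range(max_cycles):
        for i in range(p):
            d = cycle[i] - phi
            ad = -d if d < 0 else d
            if ad <= max_step:
                phi = cycle[i]
            elif d > 0:
                phi = phi + max_step
            else:
                phi = phi - max_step
            cur[i] = phi
        if it > 0:
            diff = 0.0
            for i in range(p):
                e = cur[i] - prev[i]
                if e < 0:
                    e = -e
                if e > diff:
                    diff = e
            if diff <= tol:
                return cur.copy()
        for i in range(p):
            prev[i] = cur[i]
    return np.empty(0)


def _minimal_tiling_period(values: np.ndarray) -> int:
    n = values.size
    for p in _divisors(n):
        if np.array_equal(np.tile(values[:p], n // p), values):
            return p
    return n


def cycle_fitness(env: EnvironmentSeries, tracker: TrackerSpec,
                  params: FitnessParams,
                  mean_kind: MeanKind = "geometric") -> float:
    """Mean fitness over one steady-state cycle.

    The environment is treated as periodic with its minimal tiling period;
    the tracking map is iterated (cap ``MAX_CYCLES`` cycles, window tolerance
    ``STEADY_TOL``) and the chosen mean of fitness over the final cycle is
    returned.
    """
    p = _minimal_tiling_period(env.values)
    cycle = np.ascontiguousarray(env.values[:p])
    window = _iterate_cycle(cycle, float(tracker.max_step), float(tracker.phi0),
                            STEADY_TOL, MAX_CYCLES)
    if window.size == 0:
        raise NoConvergenceError(
            f"no steady cycle within {MAX_CYCLES} cycles (max_step={tracker.max_step})"
        )
    fit = np.atleast_1d(fitness_value(window, cycle, params))
    if mean_kind == "geometric":
        return geometric_mean_fitness(fit)
    if mean_kind == "arithmetic":
        return arithmetic_mean_fitness(fit)
    raise InvalidSpecError(f"unknown mean_kind {mean_kind!r}")


def critical_gamma(env: EnvironmentSeries, fast: TrackerSpec, slow: TrackerSpec,
                   mean_kind: MeanKind = "geometric",
                   bracket: tuple[float, float] = (0.5, 64.0),
                   tol: float = 1e-6,
                   distance_scale: float = 1.0) -> float:
    """Sharpness ``gamma*`` at which the slow and fast trackers' cycle
    fitnesses cross, found by bisection on the bracket.

    Above ``gamma*`` the slow tracker strictly out-scores the fast one.
    Raises :class:`BracketError` when the fitness difference does not change
    sign over the bracket (e.g. a fast tracker that tracks perfectly always
    dominates), and :class:`InvalidSpecError` for identical step caps.
    """
    if slow.max_step == fast.max_step:
        raise InvalidSpecError("trackers are identical: fitness difference is 0")
    if slow.max_step > fast.max_step:
        raise InvalidSpecError("slow tracker must have the smaller max_step")

    def diff(gamma: float) -> float:
        params = FitnessParams(gamma=gamma, distance_scale=distance_scale)
        return (cycle_fitness(env, slow, params, mean_kind)
                - cycle_fitness(env, fast, params, mean_kind))

    lo, hi = bracket
    dlo, dhi = diff(lo), diff(hi)
    if dlo == 0.0 or dhi == 0.0 or np.sign(dlo) == np.sign(dhi):
        raise BracketError(
            f"fitness difference does not change sign over {bracket}: "
            f"({dlo:.3g}, {dhi:.3g}); widen the bracket or check dominance"
        )
    return float(bisect(diff, lo, hi, xtol=tol))


def optimal_x_landscape(env: EnvironmentSeries, params: FitnessParams,
                        x_grid, mean_kind: MeanKind = "geometric",
                        phi0: float | None = None) -> XLandscape:
    """Steady-cycle fitness per ``x`` grid point.

    ``phi0`` defaults to ``E[0]`` (a tracker initially perfectly adapted).
    Use :func:`local_maxima` to classify interior strict local maxima.
    """
    x = np.asarray(x_grid, dtype=float)
    if x.size < 3:
        raise InvalidSpecError("x_grid must have at least 3 points to classify")
    if np.any(np.diff(x) <= 0):
        raise InvalidSpecError("x_grid must be sorted strictly ascending")
    start = float(env.values[0]) if phi0 is None else phi0
    fit = np.array([
        cycle_fitness(env, TrackerSpec(max_step=float(xi), phi0=start),
                      params, mean_kind)
        for xi in x
    ])
    return XLandscape(x=x, fitness=fit)


def local_maxima(values) -> np.ndarray:
    """Indices of strict interior local maxima of a 1-D sequence."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise InvalidSpecError("need at least 3 values to classify maxima")
    interior = (v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])
    return np.flatnonzero(interior) + 1
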