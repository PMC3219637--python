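"""Stochastic dual-inheritance agent-based model.

Each agent carries a culturally inherited phenotype ``phi`` (the environment
it is adapted to) and a genetically inherited accuracy ``x`` in [0, 1] — the
probability of correctly assessing whether an available behavioral innovation
moves ``phi`` closer to the current optimum.  Per timestep:

1. one Bernoulli draw (probability ``p_behavior``) decides whether a behavior
   is available to everyone this timestep;
2. ``N`` update events, each picking an agent uniformly with replacement; the
   picked agent survives with probability equal to its fitness.  A death is
   immediately filled by the offspring of a uniformly chosen other agent
   (``phi`` copied exactly — cultural transmission; ``x`` perturbed by a
   uniform mutation on ``[-m, +m]`` and clamped to [0, 1] — genetic
   transmission).  A survivor, when a behavior is available, attempts the
   innovation: the behavior's displacement is ``±delta`` with equal
   probability, and it is adopted iff the agent assesses it (probability
   ``x``) and it strictly reduces ``|phi - E|``.

Population size is constant; extinction is impossible by construction.

RNG protocol (one ``numpy`` Generator seeded from the config): population
initialization draws first (``x`` uniforms when ``init_x="uniform"``); then
per timestep, in order: the availability uniform; the global-sign uniform
(only in ``innovation_sign="global"`` mode); and a row-major ``(N, 6)``
uniform matrix whose columns are (agent pick, survival, parent pick,
mutation, assessment, sign).  Unused draws are discarded, so the event loop
is reproducible and can be hand-stepped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .environments import EnvironmentSeries
from .errors import ConfigError
from .fitness import FitnessParams, fitness_value

#: Event-matrix column layout (see module docstring).
COL_PICK, COL_SURVIVE, COL_PARENT, COL_MUTATE, COL_ASSESS, COL_SIGN = range(6)


@dataclass(frozen=True)
class Agent:
    """One individual: phenotype ``phi`` and assessment accuracy ``x``."""

    phi: float
    x: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.x <= 1.0):
            raise ConfigError("agent accuracy x must lie in [0, 1]")


@dataclass(frozen=True)
class ABMConfig:
    """Simulation parameters.

    ``p_behavior * delta`` bounds the per-timestep rate of adaptation; the
    defaults put that bound above the slow drift of the default sawtooth
    driver but far below its single-step crash.
    """

    n_agents: int = 500
    delta: float = 0.01
    p_behavior: float = 1.0
    mutation_halfwidth: float = 0.05
    fitness: FitnessParams = field(default_factory=lambda: FitnessParams(gamma=4.0))
    init_phi: float | str = "env0"
    init_x: float | str = "uniform"
    seed: int = 0
    record_every: int = 10
    x_bins: int = 50
    innovation_sign: str = "per_agent"  # or "global": one sign per timestep

    def __post_init__(self) -> None:
        if self.n_agents < 2:
            raise ConfigError("n_agents must be >= 2 (replacement needs a parent)")
        if self.delta <= 0:
            raise ConfigError("delta must be > 0")
        if not (0.0 <= self.p_behavior <= 1.0):
            raise ConfigError("p_behavior must lie in [0, 1]")
        if self.mutation_halfwidth < 0:
            raise ConfigError("mutation_halfwidth must be >= 0")
        if isinstance(self.init_phi, str) and self.init_phi != "env0":
            raise ConfigError(f"init_phi must be a number or 'env0', got {self.init_phi!r}")
        if isinstance(self.init_x, str):
            if self.init_x != "uniform":
                raise ConfigError(f"init_x must be a number or 'uniform', got {self.init_x!r}")
        elif not (0.0 <= float(self.init_x) <= 1.0):
            raise ConfigError("constant init_x must lie in [0, 1]")
        if self.record_every < 1 or self.x_bins < 1:
            raise ConfigError("record_every and x_bins must be >= 1")
        if self.innovation_sign not in ("per_agent", "global"):
            raise ConfigError("innovation_sign must be 'per_agent' or 'global'")


@dataclass
class Population:
    """Fixed-size population stored as parallel arrays for speed."""

    phi: np.ndarray
    x: np.ndarray

    def __len__(self) -> int:
        return int(self.phi.size)

    @property
    def agents(self) -> list[Agent]:
        return [Agent(phi=float(p), x=float(a)) for p, a in zip(self.phi, self.x)]


@dataclass
class SimulationResult:
    """Recorded summaries of one run: histogram of ``x`` per recorded
    timestep (rows sum to N), population means, and full provenance."""

    recorded_t: np.ndarray
    x_hist: np.ndarray
    mean_x: np.ndarray
    mean_phi: np.ndarray
    mean_fitness: np.ndarray
    config: ABMConfig
    seed: int

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SimulationResult):
            return NotImplemented
        return (
            np.array_equal(self.recorded_t, other.recorded_t)
            and np.array_equal(self.x_hist, other.x_hist)
            and np.array_equal(self.mean_x, other.mean_x)
            and np.array_equal(self.mean_phi, other.mean_phi)
            and np.array_equal(self.mean_fitness, other.mean_fitness)
            and self.config == other.config
            and self.seed == other.seed
        )


def init_population(config: ABMConfig, rng: np.random.Generator,
                    env0: float | None = None) -> Population:
    """N agents; ``phi`` set to ``E(0)`` when ``init_phi="env0"``; ``x``
    constant or drawn uniformly on [0, 1]."""
    n = config.n_agents
    if config.init_phi == "env0":
        if env0 is None:
            raise ConfigError("init_phi='env0' requires the environment's first value")
        phi = np.full(n, float(env0))
    else:
        phi = np.full(n, float(config.init_phi))
    if config.init_x == "uniform":
        x = rng.random(n)
    else:
        x = np.full(n, float(config.init_x))
    return Population(phi=phi, x=x)


def survival_probability(agent: Agent, env_value: float,
                         params: FitnessParams) -> float:
    """Per-update-event survival probability: the fitness curve evaluated at
    the agent's phenotype (survival stands in for reproductive fitness)."""
    return fitness_value(agent.phi, env_value, params)


def adoption_probability(agent: Agent, env_value: float, delta: float) -> float:
    """Exact probability ``x * q`` that an available behavior is adopted.

    With ``d = |phi - E|``: exactly one of the two equiprobable signed moves
    strictly reduces ``d`` when ``d > delta/2`` (``q = 1/2``); neither does
    when ``d <= delta/2`` — the toward-move overshoots or ties (``q = 0``).
    """
    if delta <= 0:
        raise ConfigError("delta must be > 0")
    d = abs(agent.phi - env_value)
    q = 0.5 if d > delta / 2.0 else 0.0
    return agent.x * q


def attempt_innovation(agent: Agent, env_value: float, delta: float,
                       rng: np.random.Generator) -> Agent:
    """One innovation attempt; returns the (possibly moved) agent.

    Draw order matches the event-matrix columns: assessment uniform first,
    then sign uniform.  The move is adopted iff the agent assesses it and it
    strictly reduces the distance to the optimum.
    """
    u_assess = rng.random()
    u_sign = rng.random()
    assessed = u_assess < agent.x
    signed = delta if u_sign < 0.5 else -delta
    if assessed:
        d_old = abs(agent.phi - env_value)
        d_new = abs(agent.phi + signed - env_value)
        if d_new < d_old:
            return replace(agent, phi=agent.phi + signed)
    return agent


def reproduce(parent: Agent, mutation_halfwidth: float,
              rng: np.random.Generator) -> Agent:
    """Offspring: ``phi`` copied exactly (cultural transmission); ``x``
    perturbed by ``U(-m, +m)`` and clamped to [0, 1] (genetic transmission)."""
    u = rng.random()
    child_x = parent.x + (2.0 * u - 1.0) * mutation_halfwidth
    child_x = min(1.0, max(0.0, child_x))
    return Agent(phi=parent.phi, x=child_x)


@njit(cache=False)
def _run_events(phi, x, env_value, gamma, scale, delta, m,
                behavior_available, per_agent_sign, global_sign_u, U):  # pragma: no cover
    """N sequential update events on the population arrays (in place)."""
    n = phi.shape[0]
    for k in range(n):
        i = int(U[k, 0] * n)
        if i == n:
            i = n - 1
        d = phi[i] - env_value
        if d < 0.0:
            d = -d
        f = 1.0 / (1.0 + (d / scale) ** (2.0 * gamma))
        if U[k, 1] < f:
            if behavior_available:
                assessed = U[k, 4] < x[i]
                if per_agent_sign:
                    signed = delta if U[k, 5] < 0.5 else -delta
                else:
                    signed = delta if global_sign_u < 0.5 else -delta
                if assessed:
                    nd = phi[i] + signed - env_value
                    if nd < 0.0:
                        nd = -nd
                    if nd < d:
                        phi[i] = phi[i] + signed
        else:
            j = int(U[k, 2] * (n - 1))
            if j >= n - 1:
                j = n - 2
            if j >= i:
                j += 1
            phi[i] = phi[j]
            xm = x[j] + (2.0 * U[k, 3] - 1.0) * m
            if xm < 0.0:
                xm = 0.0
            elif xm > 1.0:
                xm = 1.0
            x[i] = xm


def step_timestep(pop: Population, env_value: float, config: ABMConfig,
                  rng: np.random.Generator) -> Population:
    """Advance the population one timestep in place (also returns it)."""
    behavior_available = rng.random() < config.p_behavior
    global_sign_u = rng.random() if config.innovation_sign == "global" else 0.0
    U = rng.random((config.n_agents, 6))
    _run_events(
        pop.phi, pop.x, float(env_value),
        config.fitness.gamma, config.fitness.distance_scale,
        config.delta, config.mutation_halfwidth,
        behavior_available, config.innovation_sign == "per_agent",
        global_sign_u, U,
    )
    return pop


def run_simulation(env: EnvironmentSeries, config: ABMConfig) -> SimulationResult:
    """Run the ABM over every timestep of ``env``; record the ``x`` histogram
    and population means every ``record_every`` steps (and at the final step).
    Bit-reproducible for a fixed config seed."""
    rng = np.random.default_rng(config.seed)
    pop = init_population(config, rng, env0=float(env.values[0]))
    T = len(env)
    rec_t, hists, mx, mphi, mfit = [], [], [], [], []
    for t in range(T):
        step_timestep(pop, env.values[t], config, rng)
        if t % config.record_every == 0 or t == T - 1:
            rec_t.append(t)
            hists.append(np.histogram(pop.x, bins=config.x_bins, range=(0.0, 1.0))[0])
            mx.append(pop.x.mean())
            mphi.append(pop.phi.mean())
            mfit.append(float(np.mean(fitness_value(pop.phi, env.values[t],
                                                    config.fitness))))
    return SimulationResult(
        recorded_t=np.array(rec_t, dtype=int),
        x_hist=np.array(hists, dtype=int),
        mean_x=np.array(mx),
        mean_phi=np.array(mphi),
        mean_fitness=np.array(mfit),
        config=config,
        seed=config.seed,
    )


def x_density_series(result: SimulationResult) -> np.ndarray:
    """Row-normalized ``x`` histogram matrix (each row sums to 1) — the
    numeric analog of the density panels used to visualize the trait."""
    counts = result.x_hist.astype(float)
    return counts / counts.sum(axis=1, keepdims=True)
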