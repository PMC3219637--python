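"""Experiment orchestration: config files, gamma sweeps over replicate
seeds, and on-disk result serialization with full provenance.

The config file is YAML with four top-level sections::

    environment:                  # required; 'kind' selects the generator
      kind: sawtooth | slow_rise_crash | icecore | file
      ...generator parameters / path, time_column, value_column
    normalize: {lower: -1, upper: 1}   # optional affine normalization
    abm: {n_agents: 500, delta: 0.01, gamma: 4.0, ...}
    gamma_list: [1, 2, 4, 8]
    seeds: [0, 1, ...]
    output_dir: results

``gamma_list`` overrides the fitness sharpness per sweep cell; every cell
uses its own seed so results are independent of execution order.  Unknown
keys anywhere are rejected.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .abm import ABMConfig, SimulationResult, run_simulation
from .environments import (
    EnvironmentSeries,
    IcecoreLikeSpec,
    SawtoothSpec,
    make_icecore_like,
    make_sawtooth,
    make_slow_rise_crash,
    normalize_series,
    read_series,
)
from .errors import ConfigError, DualsimError
from .fitness import FitnessParams

#: Fraction of the most recent recordings defining the "late epoch".
LATE_EPOCH_FRACTION = 0.2


@dataclass(frozen=True)
class ExperimentSpec:
    """A full sweep: environment recipe, base ABM config, gamma grid,
    replicate seeds, and output directory."""

    environment: dict
    abm: ABMConfig = field(default_factory=ABMConfig)
    normalize: tuple[float, float] | None = (-1.0, 1.0)
    gamma_list: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0)
    seeds: tuple[int, ...] = (0,)
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if not self.gamma_list or not self.seeds:
            raise ConfigError("gamma_list and seeds must be non-empty")
        if "kind" not in self.environment:
            raise ConfigError("environment section requires a 'kind' key")


_ENV_KEYS = {
    "sawtooth": {"rise_length", "rise_step", "crash_length", "n_cycles", "base_value"},
    "slow_rise_crash": {"rise_length", "crash_length", "n_cycles", "amplitude"},
    "icecore": {"n_cycles", "cooling_length", "deglaciation_length",
                "cooling_slope", "noise_sd", "noise_autocorr", "seed"},
    "file": {"path", "time_column", "value_column"},
}

_ABM_KEYS = {"n_agents", "delta", "p_behavior", "mutation_halfwidth", "gamma",
             "distance_scale", "init_phi", "init_x", "seed", "record_every",
             "x_bins", "innovation_sign"}

_TOP_KEYS = {"environment", "normalize", "abm", "gamma_list", "seeds", "output_dir"}


def _reject_unknown(mapping: dict, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


def _abm_from_dict(d: dict) -> ABMConfig:
    _reject_unknown(d, _ABM_KEYS, "abm section")
    d = dict(d)
    gamma = d.pop("gamma", 4.0)
    scale = d.pop("distance_scale", 1.0)
    return ABMConfig(fitness=FitnessParams(gamma=gamma, distance_scale=scale), **d)


def load_config(path) -> ExperimentSpec:
    """Parse and validate a YAML experiment file, filling documented
    defaults; unknown keys raise :class:`ConfigError` naming the key."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"could not read config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    _reject_unknown(raw, _TOP_KEYS, "top level")
    env = raw.get("environment")
    if not isinstance(env, dict) or "kind" not in env:
        raise ConfigError("config requires an 'environment' section with a 'kind'")
    kind = env["kind"]
    if kind not in _ENV_KEYS:
        raise ConfigError(f"unknown environment kind {kind!r}")
    _reject_unknown({k: v for k, v in env.items() if k != "kind"},
                    _ENV_KEYS[kind], f"environment ({kind})")
    norm = raw.get("normalize", {"lower": -1.0, "upper": 1.0})
    if norm is not None:
        _reject_unknown(norm, {"lower", "upper"}, "normalize section")
        norm = (float(norm.get("lower", -1.0)), float(norm.get("upper", 1.0)))
    try:
        abm = _abm_from_dict(raw.get("abm", {}) or {})
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    return ExperimentSpec(
        environment=dict(env),
        abm=abm,
        normalize=norm,
        gamma_list=tuple(float(g) for g in raw.get("gamma_list", (1.0, 2.0, 4.0, 8.0))),
        seeds=tuple(int(s) for s in raw.get("seeds", (0,))),
        output_dir=str(raw.get("output_dir", "results")),
    )


def save_config(spec: ExperimentSpec, path) -> None:
    """Write a spec back to YAML such that :func:`load_config` round-trips."""
    abm = spec.abm
    doc = {
        "environment": dict(spec.environment),
        "normalize": None if spec.normalize is None else
        {"lower": spec.normalize[0], "upper": spec.normalize[1]},
        "abm": {
            "n_agents": abm.n_agents,
            "delta": abm.delta,
            "p_behavior": abm.p_behavior,
            "mutation_halfwidth": abm.mutation_halfwidth,
            "gamma": abm.fitness.gamma,
            "distance_scale": abm.fitness.distance_scale,
            "init_phi": abm.init_phi,
            "init_x": abm.init_x,
            "seed": abm.seed,
            "record_every": abm.record_every,
            "x_bins": abm.x_bins,
            "innovation_sign": abm.innovation_sign,
        },
        "gamma_list": list(spec.gamma_list),
        "seeds": list(spec.seeds),
        "output_dir": spec.output_dir,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def build_environment(spec: ExperimentSpec) -> EnvironmentSeries:
    """Materialize the environment named in the spec, applying the optional
    normalization."""
    env_cfg = dict(spec.environment)
    kind = env_cfg.pop("kind")
    if kind == "sawtooth":
        env = make_sawtooth(SawtoothSpec(**env_cfg))
    elif kind == "slow_rise_crash":
        env = make_slow_rise_crash(**env_cfg)
    elif kind == "icecore":
        env = make_icecore_like(IcecoreLikeSpec(**env_cfg))
    elif kind == "file":
        env = read_series(env_cfg["path"], env_cfg["time_column"],
                          env_cfg["value_column"])
    else:
        raise ConfigError(f"unknown environment kind {kind!r}")
    if spec.normalize is not None:
        env = normalize_series(env, *spec.normalize)
    return env


def late_epoch_mean(series: np.ndarray,
                    fraction: float = LATE_EPOCH_FRACTION) -> float:
    """Mean over the final ``fraction`` of recorded values (at least one)."""
    n = len(series)
    k = max(1, int(np.ceil(fraction * n)))
    return float(np.mean(series[n - k:]))


def value_at(result: SimulationResult, statistic: str, t: int) -> float:
    """Value of a recorded statistic at the first recording at or after
    timestep ``t`` (clipped to the final recording)."""
    series = getattr(result, statistic)
    idx = int(np.searchsorted(result.recorded_t, t))
    idx = min(idx, len(result.recorded_t) - 1)
    return float(series[idx])


def write_result(result: SimulationResult, out_dir) -> None:
    """Write ``result.csv`` (long: t, statistic, value), ``x_hist.csv``
    (t then per-bin counts) and ``meta.json`` (config echo, seed, version)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for stat in ("mean_x", "mean_phi", "mean_fitness"):
        vals = getattr(result, stat)
        rows.extend(
            {"t": int(t), "statistic": stat, "value": v}
            for t, v in zip(result.recorded_t, vals)
        )
    pd.DataFrame(rows).to_csv(out / "result.csv", index=False)
    hist = pd.DataFrame(
        result.x_hist,
        columns=[f"bin_{i}" for i in range(result.x_hist.shape[1])],
    )
    hist.insert(0, "t", result.recorded_t)
    hist.to_csv(out / "x_hist.csv", index=False)
    cfg = dataclasses.asdict(result.config)
    meta = {"config": cfg, "seed": result.seed, "version": __version__}
    with open(out / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def read_result(out_dir) -> SimulationResult:
    """Reload a directory written by :func:`write_result` into an object
    equal to the original."""
    out = Path(out_dir)
    long = pd.read_csv(out / "result.csv", float_precision="round_trip")
    hist = pd.read_csv(out / "x_hist.csv")
    with open(out / "meta.json") as fh:
        meta = json.load(fh)
    cfg = dict(meta["config"])
    fit = cfg.pop("fitness")
    config = ABMConfig(fitness=FitnessParams(**fit), **cfg)
    rec_t = hist["t"].to_numpy(dtype=int)

    def stat(name: str) -> np.ndarray:
        s = long[long["statistic"] == name].sort_values("t")
        return s["value"].to_numpy(dtype=float)

    return SimulationResult(
        recorded_t=rec_t,
        x_hist=hist.drop(columns="t").to_numpy(dtype=int),
        mean_x=stat("mean_x"),
        mean_phi=stat("mean_phi"),
        mean_fitness=stat("mean_fitness"),
        config=config,
        seed=int(meta["seed"]),
    )


def run_experiment(spec: ExperimentSpec, write: bool = True):
    """Run ``len(gamma_list) x len(seeds)`` simulations.

    Returns ``(results, summary, failures)``: a dict keyed by
    ``(gamma, seed)``, a summary DataFrame with one row per cell
    (gamma, seed, late-epoch mean_x and mean_fitness), and a list of
    ``(gamma, seed, message)`` for cells that failed (remaining cells still
    run).  With ``write=True`` each cell is written under
    ``output_dir/gamma{g}_seed{s}`` plus a ``summary.csv``.
    """
    env = build_environment(spec)
    results: dict[tuple[float, int], SimulationResult] = {}
    rows = []
    failures: list[tuple[float, int, str]] = []
    out = Path(spec.output_dir)
    for gamma in spec.gamma_list:
        for seed in spec.seeds:
            cfg = dataclasses.replace(
                spec.abm,
                fitness=FitnessParams(gamma=gamma,
                                      distance_scale=spec.abm.fitness.distance_scale),
                seed=int(seed),
            )
            try:
                res = run_simulation(env, cfg)
            except DualsimError as exc:
                failures.append((gamma, int(seed), str(exc)))
                continue
            results[(gamma, int(seed))] = res
            rows.append({
                "gamma": gamma,
                "seed": int(seed),
                "late_mean_x": late_epoch_mean(res.mean_x),
                "late_mean_fitness": late_epoch_mean(res.mean_fitness),
            })
            if write:
                write_result(res, out / f"gamma{gamma:g}_seed{seed}")
    summary = pd.DataFrame(rows)
    if write:
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "summary.csv", index=False)
    return results, summary, failures
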