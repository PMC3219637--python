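"""Environmental drivers: sawtooth generators, an ice-core-like emulator,
file import with interpolation onto a unit-time grid, normalization, and
reversal detection.

The environment is a single scalar optimum ``E(t)``, one value per timestep.
Timesteps are 0-based; a series of length ``T`` covers ``t = 0 .. T-1``.
All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    CannotInterpolateError,
    DegenerateRangeError,
    InvalidSpecError,
    ParseError,
)

#: Default affine normalization range, symmetric about 0 so a full-range
#: crash puts an agent at distance 2 from the optimum (see the fitness module).
DEFAULT_NORM_RANGE = (-1.0, 1.0)


@dataclass(frozen=True)
class EnvironmentSeries:
    """The exogenous driver E(t), one value per timestep.

    Parameters
    ----------
    values
        Environmental optimum per timestep, dimensionless after normalization.
    timestep_label
        Unit of one timestep (e.g. ``"year"``, ``"step"``).
    normalized
        Whether :func:`normalize_series` has been applied.
    raw_range
        ``(min, max)`` of the pre-normalization series, recorded by
        :func:`normalize_series`.
    """

    values: np.ndarray
    timestep_label: str = "step"
    normalized: bool = False
    raw_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise InvalidSpecError("environment series must be 1-D with length >= 1")
        if not np.all(np.isfinite(v)):
            raise InvalidSpecError("environment series contains non-finite values")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EnvironmentSeries):
            return NotImplemented
        return (
            np.array_equal(self.values, other.values)
            and self.timestep_label == other.timestep_label
            and self.normalized == other.normalized
            and self.raw_range == other.raw_range
        )


@dataclass(frozen=True)
class SawtoothSpec:
    """Discrete sawtooth: ``rise_length`` increments of ``rise_step`` from
    ``base_value``, then a return to ``base_value`` over ``crash_length`` steps
    (1 = single-step crash, realized as the start of the next cycle)."""

    rise_length: int
    rise_step: float
    crash_length: int = 1
    n_cycles: int = 1
    base_value: float = 0.0

    def __post_init__(self) -> None:
        if self.rise_length < 1 or self.crash_length < 1 or self.n_cycles < 1:
            raise InvalidSpecError("sawtooth lengths and n_cycles must be >= 1")
        if self.rise_step < 0:
            raise InvalidSpecError("rise_step must be >= 0")


@dataclass(frozen=True)
class IcecoreLikeSpec:
    """Ice-core-like driver: long slow cooling, rapid deglaciation, plus
    additive stationary AR(1) noise.  See ``default_icecore_spec`` for the
    package defaults emulating four glacial cycles."""

    n_cycles: int = 4
    cooling_length: int = 800
    deglaciation_length: int = 25
    cooling_slope: float = -0.0025
    noise_sd: float = 0.05
    noise_autocorr: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cycles < 1 or self.cooling_length < 1 or self.deglaciation_length < 1:
            raise InvalidSpecError("cycle counts and phase lengths must be >= 1")
        if self.deglaciation_length >= self.cooling_length:
            raise InvalidSpecError("deglaciation must be shorter than cooling")
        if self.cooling_slope >= 0:
            raise InvalidSpecError("cooling_slope must be < 0")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")
        if not (0.0 <= self.noise_autocorr < 1.0):
            raise InvalidSpecError("noise_autocorr must lie in [0, 1)")


@dataclass(frozen=True)
class ReversalEvent:
    """A detected rapid reversal: the timestep at which the windowed change
    first exceeded the threshold, and the signed change over that window."""

    timestep: int
    magnitude: float


def _sawtooth_cycle(rise_length: int, rise_step: float, crash_length: int,
                    base_value: float) -> np.ndarray:
    # Rise occupies indices 0..rise_length (rise_length+1 points including the
    # base); a crash_length-step crash contributes crash_length-1 interior
    # points, the final step landing on the next cycle's base.
    rise = base_value + rise_step * np.arange(rise_length + 1, dtype=float)
    peak = base_value + rise_step * rise_length
    k = np.arange(1, crash_length, dtype=float)
    crash = peak - (peak - base_value) * k / crash_length
    return np.concatenate([rise, crash])


def make_sawtooth(spec: SawtoothSpec) -> EnvironmentSeries:
    """Discrete sawtooth series, e.g. ``[0,1,2,3,0,1,2,3]`` for
    ``rise_length=3, rise_step=1, crash_length=1, n_cycles=2``.

    Length is ``n_cycles * (rise_length + crash_length)``.
    """
    cycle = _sawtooth_cycle(spec.rise_length, spec.rise_step,
                            spec.crash_length, spec.base_value)
    return EnvironmentSeries(np.tile(cycle, spec.n_cycles))


def make_slow_rise_crash(rise_length: int, crash_length: int, n_cycles: int,
                         amplitude: float) -> EnvironmentSeries:
    """Continuous sawtooth from ``-amplitude`` to ``+amplitude`` linearly over
    ``rise_length`` steps, crashing back over ``crash_length`` steps, repeated
    ``n_cycles`` times.  Per-step rise slope is ``2*amplitude/rise_length``."""
    if amplitude <= 0:
        raise InvalidSpecError("amplitude must be > 0")
    spec = SawtoothSpec(
        rise_length=rise_length,
        rise_step=2.0 * amplitude / rise_length,
        crash_length=crash_length,
        n_cycles=n_cycles,
        base_value=-amplitude,
    )
    return make_sawtooth(spec)


def make_icecore_like(spec: IcecoreLikeSpec) -> EnvironmentSeries:
    """Piecewise-linear slow-cooling / fast-warming sawtooth plus seeded
    stationary AR(1) noise.  ``noise_sd=0`` gives the exact sawtooth."""
    trend = make_sawtooth(
        SawtoothSpec(
            rise_length=spec.cooling_length,
            rise_step=abs(spec.cooling_slope),
            crash_length=spec.deglaciation_length,
            n_cycles=spec.n_cycles,
            base_value=0.0,
        )
    ).values
    # Cooling means the trend falls: flip sign so the slow phase descends and
    # the deglaciation phase is the rapid rise back toward the warm state.
    trend = -trend
    if spec.noise_sd == 0:
        return EnvironmentSeries(trend, timestep_label="year")
    rng = np.random.default_rng(spec.seed)
    a = spec.noise_autocorr
    n = trend.size
    noise = np.empty(n)
    noise[0] = rng.normal(0.0, spec.noise_sd)
    innov = rng.normal(0.0, spec.noise_sd * np.sqrt(1.0 - a * a), size=n - 1)
    for t in range(1, n):
        noise[t] = a * noise[t - 1] + innov[t - 1]
    return EnvironmentSeries(trend + noise, timestep_label="year")


def read_series(path, time_column: str, value_column: str) -> EnvironmentSeries:
    """Read a two-column delimited file and interpolate onto a unit-time grid.

    The file must be CSV or TSV with a header naming both columns.  Rows are
    sorted ascending in time; values are linearly interpolated onto integer
    multiples of one time unit spanning the observed range, matching drivers
    where one timestep is one year.
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"could not read {path}: {exc}") from exc
    for col in (time_column, value_column):
        if col not in df.columns:
            raise ParseError(f"column {col!r} not found in {path}")
    sub = df[[time_column, value_column]]
    numeric = sub.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(f"non-numeric cell in {path} at data row {row}")
    if len(numeric) < 2:
        raise CannotInterpolateError("need at least 2 rows to interpolate")
    numeric = numeric.sort_values(time_column)
    t = numeric[time_column].to_numpy(dtype=float)
    v = numeric[value_column].to_numpy(dtype=float)
    grid = np.arange(t[0], t[-1] + 1e-9)
    values = np.interp(grid, t, v)
    return EnvironmentSeries(values, timestep_label="year")


def normalize_series(env: EnvironmentSeries,
                     lower: float = DEFAULT_NORM_RANGE[0],
                     upper: float = DEFAULT_NORM_RANGE[1]) -> EnvironmentSeries:
    """Affine map sending the series minimum to ``lower`` and maximum to
    ``upper`` exactly; order-preserving everywhere.  Idempotent when the
    series already spans ``[lower, upper]``."""
    if upper <= lower:
        raise InvalidSpecError("upper bound must exceed lower bound")
    v = env.values
    vmin, vmax = float(v.min()), float(v.max())
    if vmin == vmax:
        raise DegenerateRangeError("constant series: normalization undefined")
    if vmin == lower and vmax == upper:
        mapped = v.copy()
    else:
        scale = (upper - lower) / (vmax - vmin)
        mapped = lower + (v - vmin) * scale
        # force bit-exact extremes regardless of rounding
        mapped[v == vmin] = lower
        mapped[v == vmax] = upper
    return EnvironmentSeries(
        mapped,
        timestep_label=env.timestep_label,
        normalized=True,
        raw_range=(vmin, vmax),
    )


def detect_reversals(env: EnvironmentSeries, window: int,
                     threshold: float) -> list[ReversalEvent]:
    """Timesteps where the change over ``window`` steps opposes the trailing
    long-run trend and exceeds ``threshold`` in magnitude.

    The trailing trend is the net change over up to ``5 * window`` steps
    preceding the detection window.  Events are reported greedily
    earliest-first and separated by at least ``window`` steps.
    """
    if threshold <= 0:
        raise InvalidSpecError("threshold must be > 0")
    v = env.values
    n = v.size
    if window < 1 or window >= n:
        raise InvalidSpecError("window must satisfy 1 <= window < len(series)")
    events: list[ReversalEvent] = []
    t = window
    trail = 5 * window
    while t < n:
        change = v[t] - v[t - window]
        lo = max(0, t - window - trail)
        trend = v[t - window] - v[lo]
        if abs(change) > threshold and trend != 0 and np.sign(change) == -np.sign(trend):
            events.append(ReversalEvent(timestep=int(t), magnitude=float(change)))
            t += window
        else:
            t += 1
    return events


def write_series(env: EnvironmentSeries, path) -> None:
    """Write the series as a two-column CSV (t, E)."""
    pd.DataFrame({"t": np.arange(len(env)), "E": env.values}).to_csv(path, index=False)


def write_reversals(events: list[ReversalEvent], path) -> None:
    """Write detected reversal events as CSV (timestep, magnitude)."""
    pd.DataFrame(
        {
            "timestep": [e.timestep for e in events],
            "magnitude": [e.magnitude for e in events],
        }
    ).to_csv(path, index=False)
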