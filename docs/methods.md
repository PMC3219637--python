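# Methods

## Model overview

The package studies a single scalar environment `E(t)` and agents described
by a phenotype `φ` (the environmental value they are best adapted to) and an
accuracy `x`.  Two models share the same fitness curve:

* a **deterministic tracker** (analytical model): one immortal agent whose
  phenotype moves toward the current optimum by at most `x` per timestep —
  accuracy as a movement cap, no reproduction or selection;
* a **stochastic dual-inheritance population** (agent-based model):
  accuracy as the probability of correctly assessing a candidate behavior,
  with survival selection, cultural inheritance of `φ`, and genetic
  inheritance of `x`.

Both models assume agents cannot forecast the environment and keep no
repertoire of past behaviors; adaptation is a greedy, memoryless walk toward
the current optimum.  These assumptions are what make sudden reversals
dangerous for accurate agents.

## Fitness curve

Fitness is a function of the distance `d = |φ − E|`:

    f(d) = 1 / (1 + (d / s)^(2γ)),   γ > 0, s > 0.

Properties: `f(0) = 1` (and only there), `f(s) = 1/2` for every `γ`, the
curve is symmetric, strictly decreasing in `d`, strictly positive (so
geometric means are always defined), and Gaussian-like in shape while being
cheap to evaluate.  Raising `γ` sharpens the threshold at `d = s`: fitness
inside the scale improves, fitness beyond it collapses — e.g. at `d = 2`,
`f = 1/(1+2^{2γ})`, about `1.5 × 10⁻⁵` for `γ = 8`.  This family is this
package's concrete choice of distance-based threshold curve; any curve with
the properties above produces the same qualitative behavior, and the module
isolates it behind one function so an alternative form is a one-line swap.

Survival in the agent-based model uses the same curve as a per-update
survival probability; survival-based bookkeeping is cheaper than explicit
reproductive fitness and preserves the shape of selection.

Aggregation over time defaults to the geometric mean, `exp(mean(log f))`,
the quantity long-run selection maximizes in fluctuating environments; the
arithmetic mean is provided for comparison.  AM ≥ GM with equality only for
constant fitness, which is why variance in fitness is penalized.

## Environments

* `make_sawtooth`: `rise_length` increments of `rise_step` from
  `base_value`, returning over `crash_length` steps (a single-step crash is
  realized as the jump into the next cycle).  The worked cycle-4 example is
  `[0, 1, 2, 3]` repeating.
* `make_slow_rise_crash`: continuous sawtooth from −amplitude to +amplitude;
  the default study driver rises 300 steps (slope `2/300 ≈ 0.0067`) and
  crashes in one step (magnitude 2).
* `make_icecore_like`: slow linear cooling, rapid linear deglaciation, plus
  stationary AR(1) noise (`noise[t] = a·noise[t−1] + ε`, innovation variance
  `σ²(1−a²)` so the stationary sd is `noise_sd`).  Defaults: 4 cycles of
  800-step cooling at slope −0.0025 and 25-step deglaciation, `noise_sd`
  0.05, lag-1 autocorrelation 0.8.  After normalization to [−1, 1] the
  cooling slope (≈ 0.0025/step) sits below the maximal behavioral tracking
  rate of the default ABM (p·δ/2 = 0.005/step) while deglaciation
  (≈ 0.08/step) far exceeds it — slow drift that can be tracked, reversals
  that cannot, with red-noise texture.  This emulates the shape of an
  ice-core temperature record (slow glaciation, fast deglaciation), not its
  physics: no deuterium-to-temperature calibration, no orbital forcing, and
  the real record's irregular cycle lengths and plateaus are absent.  Tests
  passing on this driver show the mechanism operates under ice-core-like
  geometry, not that it operated in any particular paleoclimate.
* `read_series`: two-column delimited import, sorted in time and linearly
  interpolated onto a unit-time grid (one timestep = one time unit, e.g. a
  year).  Whether to interpolate or hold values between irregular samples is
  a genuine choice; linear interpolation is the default and the import path
  is invariant to affine transformations of the raw values once normalized.
* `normalize_series`: affine map with exact endpoint handling ([−1, +1]
  default, configurable).  Constant series are rejected (degenerate range).
* `detect_reversals`: a windowed change opposing the trailing trend (net
  change over the preceding `5·window` steps) and exceeding a threshold;
  greedy earliest-first with at-least-`window` separation.  This is an
  analysis instrument of this package, with defaults `window = 10`,
  threshold = half the series range.

## Deterministic tracker

Event order within a timestep: the environment takes its value `E[t]`, the
agent moves toward it by `min(x, |E[t] − φ|)` (landing exactly when within
reach; staying put at zero distance), and fitness is evaluated post-move.
The alternative move-then-observe order is available as a switch for
sensitivity checks.  With `φ(0) = E(0)` the agent starts perfectly adapted.

Steady cycles: the map is iterated cycle by cycle until two successive
cycle-length phenotype windows agree within 1e−12 (cap 10,000 cycles).
Because the tracker lands exactly on targets within reach, trajectories
enter exact periodicity in finite time for every tested `x`; the steady
period equals the environment period for all partial trackers, with the
frozen tracker (`x = 0`) reported as a degenerate period-1 case.

`critical_gamma` brackets and bisects the difference of the two trackers'
cycle fitnesses (default bracket (0.5, 64), tolerance 1e−6 on γ).  A fast
tracker that can cover the crash tracks perfectly, scores 1 identically, and
yields no crossing — reported as a bracket error rather than a number.

`optimal_x_landscape` evaluates cycle fitness on an `x` grid.  On crash
environments the landscape is bimodal: a narrow interior peak at small `x`
(trackers that lag the drift and stay near the long-term mean) separated by
a valley (trackers fast enough to hug the rise, stranded by the crash) from
the boundary regime of very fast trackers that recover within a step or two.
When the grid cannot reach crash-covering speeds, the interior peak is the
relevant optimum.  Local maxima are classified strictly
(`f[i−1] < f[i] > f[i+1]`) and confirmed by 10× grid refinement around the
candidate.

## Agent-based model

Per timestep: one Bernoulli draw (probability `p_behavior`) decides whether
a behavioral innovation is available to everyone; then `N` update events,
each choosing an agent uniformly **with replacement**.  The chosen agent
survives with probability `f(|φ − E|)`.  On death, a uniformly chosen other
agent reproduces into the slot: the child's `φ` is a bit-exact copy
(cultural transmission — no mutation, so all movement of `φ` toward the
optimum is due to choice, not blind variation), and the child's `x` is the
parent's plus `U(−m, +m)`, clamped to [0, 1] (genetic transmission).  On
survival, if a behavior is available, the agent attempts it: the behavior
shifts `φ` by ±δ with equal probability, and is adopted iff the agent
assesses it (probability `x`) *and* it strictly reduces the distance to the
optimum — ties (distance exactly δ/2) are rejected.  A newly born agent does
not innovate within the event that created it; an agent sampled several
times in one timestep undergoes several independent events.  The population
size never changes, so extinction is impossible by construction.

The innovation's sign is drawn per agent attempt by default (keeping agents
exchangeable); a `global` switch draws one sign per timestep for sensitivity
analysis, since either reading of "a new behavior becomes available" is
defensible.

Defaults: `N = 500`, `δ = 0.01`, `p_behavior = 1`, `m = 0.05`,
`record_every = 10`, `x_bins = 50`, `φ` initialized at `E(0)`, `x` uniform
on [0, 1].  The product `p·δ = 0.01` bounds the per-step adaptation rate
from above (the expected rate at full accuracy is `p·δ/2`); it exceeds the
slow-phase slope of the default driver (≈ 0.0067) but is hopeless against
its single-step crash of magnitude 2 — the regime in which even maximal
foresight cannot track the reversal, which is the precondition for
intermediate accuracy to win.  The recorded outputs are the `x` histogram
(the numeric analog of the density panels used to visualize the trait),
and population means of `x`, `φ`, and fitness.

RNG protocol: one `numpy` Generator per run, seeded from the config.
Initialization draws first; each timestep then draws the availability
uniform, the global-sign uniform (global mode only), and a row-major
`(N, 6)` matrix with columns (agent pick, survival, parent pick, mutation,
assessment, sign); unused entries are discarded.  Fixing the draw schedule
makes runs bit-reproducible, makes the event loop jittable, and lets a
hand-stepped reference implementation reproduce a timestep exactly (the
micro-oracle test at `N = 3`).

## Experiment orchestration

`run_experiment` runs a γ × seed grid; every cell gets its own seed, so
results are independent of execution order, and seed-matched comparisons
across γ are paired.  The scalar summary "late-epoch mean `x`" is the mean
of `mean_x` over the final 20% of recordings — a run-level number standing
in for the terminal trait distribution.  In sweep analyses, a per-seed
"decreasing trend" across the γ grid is scored as a negative rank
correlation between γ and late-epoch mean `x`.

Outputs carry full provenance (config echo, seed, package version) and
round-trip exactly (`float_precision="round_trip"` on re-read).

## Problem sizes and numerical choices

Study conditions used by the tests and the acceptance script: the cycle-4
sawtooth for all critical-γ work; a 20-step 0.1/step rise with unit crash
for the landscape (grid step 0.01 on [0, 1.5]); 10 cycles of the 300-step
continuous driver with 10 replicate seeds per γ ∈ {1, 2, 4, 8}; the default
4-cycle ice-core-like driver with 10 seeds at γ = 8, post-reversal windows
from 25 steps before to 75 steps after a detected reversal and slow-phase
windows of 400 steps inside each cooling phase.  Brute-force oracles use
100–200 explicit cycles.  Bisection tolerance 1e−6 on γ; steady-window
tolerance 1e−12; all statistical acceptance checks at α = 0.05.

## Known limitations

* The analytical claims (existence of γ*, interior local optimum, cyclical
  steady states) are verified numerically on concrete environments, not
  proved symbolically.
* The interior optimum's location depends on the grid and on `φ(0)`; the
  landscape is jagged at fine scales because steady cycles change
  discontinuously with `x`.
* The ABM's late-epoch mean `x` is noisy across seeds near the transition
  (γ ≈ 4); conclusions are framed as rank statistics over replicate seeds.
* No energetic cost of accuracy, no forecasting, no memory, no social
  learning beyond parent→child, no spatial structure.
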