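# dualsim

Dual-inheritance simulation of *directed innovation* in fluctuating
environments: when is it adaptive to be **less** accurate at choosing
fitness-enhancing behaviors?

## The problem

Some animals can assess whether a candidate behavior will fit them better to
the current environment, adopt it if so, and pass the learned behavior to
their offspring — directed innovation under cultural inheritance, in contrast
to blind mutation.  Intuition says more accuracy is always better.  But in an
environment that drifts slowly in one direction and then reverses abruptly
toward its long-term mean (a sawtooth), a highly accurate lineage tracks the
drift so closely that the reversal strands it far from the optimum, while a
sluggish lineage that hovered near the mean sails through.  Because long-run
selection maximizes the *geometric* mean fitness over time — which punishes
variance — one catastrophic timestep can outweigh a long stretch of superior
adaptation, and intermediate accuracy can be locally optimal.

`dualsim` is for modellers who want to explore that mechanism quantitatively.
It provides:

* **environments** — sawtooth and ice-core-like synthetic drivers, import of
  any two-column time series (interpolated to a unit-time grid), affine
  normalization to a fixed range ([−1, +1] by default), reversal detection;
* **fitness** — the distance-based fitness curve
  `f(φ, E) = 1 / (1 + (|φ − E| / s)^(2γ))` with sharpness `γ` and
  half-fitness distance `s` (default 1), plus arithmetic/geometric
  aggregation;
* **analytical** — a deterministic tracker that moves its phenotype `φ`
  toward the optimum by at most `x` per step: steady cycles, per-cycle mean
  fitness, the critical sharpness `γ*` at which a slower tracker overtakes a
  faster one, and the fitness landscape over `x` with its interior local
  optimum;
* **abm** — a stochastic fixed-size population (survival-replacement
  updates) in which behavior `φ` is culturally inherited (copied exactly)
  and the assessment accuracy `x ∈ [0, 1]` is genetically inherited with
  bounded uniform mutation;
* **interface / CLI** — YAML-configured γ × seed sweeps with full
  provenance (`dualsim env-gen | env-import | analytic-sweep | abm-run |
  experiment`).

## Worked example

```python
from dualsim import (ABMConfig, FitnessParams, SawtoothSpec, TrackerSpec,
                     critical_gamma, cycle_fitness, make_sawtooth,
                     make_slow_rise_crash, run_simulation)
from dualsim.interface import late_epoch_mean

# deterministic model on the cycle-4 sawtooth [0, 1, 2, 3, 0, 1, 2, 3, ...]
env = make_sawtooth(SawtoothSpec(rise_length=3, rise_step=1.0))
fast, slow = TrackerSpec(max_step=1.0), TrackerSpec(max_step=0.25)
print(f"critical gamma: {critical_gamma(env, fast, slow):.4f}")
for g in (2.0, 6.0):
    p = FitnessParams(g)
    print(f"  gamma={g:g}: fast={cycle_fitness(env, fast, p):.4f} "
          f"slow={cycle_fitness(env, slow, p):.4f}")

# agent-based model on a slow 300-step rise with a single-step crash
driver = make_slow_rise_crash(rise_length=300, crash_length=1,
                              n_cycles=10, amplitude=1.0)
for g in (1.0, 8.0):
    res = run_simulation(driver, ABMConfig(seed=0, fitness=FitnessParams(g)))
    print(f"ABM gamma={g:g}: late-epoch mean x = {late_epoch_mean(res.mean_x):.3f}")
```

prints

```
critical gamma: 3.2280
  gamma=2: fast=0.4925 slow=0.4368
  gamma=6: fast=0.1250 slow=0.1478
ABM gamma=1: late-epoch mean x = 0.899
ABM gamma=8: late-epoch mean x = 0.281
```

Below `γ* ≈ 3.23` the fast tracker (`x = 1`) has the higher geometric-mean
cycle fitness; above it the slow tracker (`x = 0.25`) wins, because the fast
tracker sits at distance 2 from the optimum right after each crash and the
sharper curve makes that one step ruinous.  The same mechanism drives the
evolutionary result: with a gentle curve (`γ = 1`) the population evolves
near-maximal accuracy (mean `x ≈ 0.9`), while with a sharp curve (`γ = 8`)
each crash wipes out the closest trackers and the population settles at an
intermediate accuracy (mean `x ≈ 0.3`).

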