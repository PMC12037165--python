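# graspcode

Analysis pipeline for **time-varying encoding of grip type and pulling
force in motor-cortex populations** during a delayed reach-to-grasp task.

In the task a monkey rests its hand on a switch; a 300 ms visual cue
instructs the grip (side or precision), and after a 1,000 ms delay a second
cue gives the required pulling-force level (low or high) and serves as the
go signal. The animal reaches, grasps, and pulls the object for at least
500 ms. Because grip is cued before the delay and force only at go, grip
can be prepared while force must be programmed "on the go" — making this
design a natural probe of how the two movement parameters are encoded, and
for how long, in primary motor cortex.

The package implements the full analysis chain for such sessions, plus a
synthetic-session generator so every stage is testable without recorded
data:

- **`synthetic`** — task-structured trial tables, inhomogeneous-Poisson
  spike trains with configurable grip/force/time coding (static or dynamic
  schemes), and pulling-force traces.
- **`rates`** — causal exponential filtering (τ = 100 ms, 20 ms steps) and
  100 ms count windows stepped every 80 ms (51 bins over ±2 s around
  movement onset).
- **`single_unit`** — time-resolved auROC selectivity per unit
  (auROC(t) = P(rate_A > rate_B) + ½P(tie); Δ = |auROC − 0.5|), label-
  permutation significance (p < 0.001, ≥2 consecutive bins), selectivity
  classes (grip-only / force-only / mixed / none), a permuted-χ² marginal
  independence test, covariance-ellipse orientation (θ ≈ 90° ⇒ independent
  codes), and ΔauROC strength/cross-temporal correlations (lags ±400 ms).
- **`dpca`** — demixed PCA: the unit × grip × force × time tensor is split
  into time/grip/force/interaction marginalizations that sum exactly to the
  centered tensor; reduced-rank ridge regression yields decoder/encoder
  axes per marginalization with explained-variance accounting; single-trial
  nearest-class-mean classifiers with a 100-shuffle Monte Carlo chance
  distribution (significance: ≥10 consecutive winning bins).
- **`decoding`** — per-bin linear max-margin decoding (50 repetitions of
  25-train/5-test splits per class), the cross-temporal train × test
  accuracy matrix, the three-condition *static-bin* criterion
  (cluster-based permutation p < 0.01, 99th-percentile bootstrap null
  exceedance, Bonferroni-significant diagonal bins), and the
  *generalization index*: per test bin, the fraction of train bins inside
  the preparation or execution epoch whose decoding is static.
- **`behavior`** — RT/MT summaries with rank-sum comparison, and trialwise
  force-trace / component cross-correlations with a circular-shift null and
  a two-way ANOVA (component family × force level).
- **`io_core` / `pipeline` / `report`** — TSV + HDF5 serialization, a
  stage-keyed result store with provenance, INI configs, and figure/manifest
  assembly.

## Worked example

```python
import numpy as np
from graspcode import (TaskConfig, generate_trials, make_population,
                       simulate_spikes, smooth_rates)
from graspcode import single_unit as su

trials = generate_trials(TaskConfig(n_trials_per_condition=30, seed=0))
pop = make_population(n_grip_only=8, n_mixed=4, n_force_only=1, n_null=7,
                      gain=0.5, time_amp=1.0, seed=1)
spikes = simulate_spikes(trials, pop, seed=2)
sm = smooth_rates(spikes, trials)          # causal exponential filter, tau=100 ms
grip = trials["grip"].to_numpy() == "side"
force = trials["force"].to_numpy() == "high"
res_g = su.permutation_mask(sm.rates, grip, sm.bin_centers, n_perm=2000, rng=3)
res_f = su.permutation_mask(sm.rates, force, sm.bin_centers, n_perm=2000, rng=4)
labels, counts = su.classify_selectivity(res_g, res_f)
print("selectivity counts:", counts)
peak = sm.bin_centers[np.argmax(res_g.delta.mean(axis=0))]
print("peak mean grip dauROC: %.3f at %+d ms from movement onset"
      % (res_g.delta.mean(axis=0).max(), peak))
theta, _, _ = su.ellipse_angle(
    np.column_stack([res_f.auroc[:, 150], res_g.auroc[:, 150]]))
print("auROC scatter ellipse angle at +1000 ms: %.1f deg" % theta)
```

prints

```
selectivity counts: {'grip_only': 8, 'force_only': 1, 'mixed': 4, 'none': 7}
peak mean grip dauROC: 0.290 at -440 ms from movement onset
auROC scatter ellipse angle at +1000 ms: 72.7 deg
```

All 13 planted selective units (and none of the null units) are recovered
with their designed classes; grip modulation peaks before movement onset
because the grip cue precedes the delay; and the near-vertical ellipse says
grip-modulation direction does not covary with force preference.

The same analyses run end-to-end from the command line:

```sh
graspcode simulate --seed 1 --out dataset
graspcode run --seed 1 --out results            # or --input dataset
graspcode report --in results --out report      # figures + manifest.json
```

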