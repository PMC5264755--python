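# placenav

Goal-directed path finding on a cognitive map of hippocampal place cells,
navigated by the gradient of a neural energy field.

A rodent exploring a new environment builds a map out of place cells — each
fires most strongly when the animal occupies that cell's *place field*. This
package simulates how such a map, once seeded by a single random physical
search, can be refined by cheap *mental* explorations: simulated traversals
of the map that find increasingly direct routes to a remembered target
without further physical cost. It is aimed at computational-neuroscience
users who want a small, fully reproducible test bed for energy-coding /
gradient-navigation ideas.

## Model

- **Place-cell lattice.** n = rows x cols place cells, one per node of a
  regular lattice (reference setup: 15 x 15 = 225 cells, spacing 1). Each
  cell is synaptically connected to its four neighbours.
- **Firing power.** An isolated cell with place-field center (mu1, mu2)
  fires with power

  P0(x, y) = 1/(2 pi sigma1 sigma2) * exp{-1/2 [((x-mu1)/sigma1)^2 + ((y-mu2)/sigma2)^2]},

  the unique form compatible with axis-independence and rotational
  symmetry; it integrates to 1 over the plane. Excitatory synapses scale a
  cell's power by (1 + omega_ti + sum_j omega_ji).
- **Hebbian energy learning (LTP only).** When the nearest cell changes
  from j to i across a step, the directed weight gains
  d(omega_ji) = eta * P_j * P_i — the product of the two firing powers at
  the moments before and after the step. Weights never decay; the rule is
  deliberately non-convergent, which at small sigma produces the "siege"
  failure mode (the path gets trapped in an over-strengthened region).
- **Energy field and navigation.** At every step k the field over all
  place-field centers is

  P_k(x, y) = (1 + sum_j omega_ji) * G(x, y; current position) + G(x, y; target),

  the target term switching on once the target has been discovered. The
  next step's direction is the normalised sum of the field's discrete
  gradient (central differences on the lattice) and a random disturbance
  with uniformly distributed direction:

  n_{k+1} = (grad P_k + n_rand) / |grad P_k + n_rand|.

  Trial 1 is a completely random search; from trial 2 on, navigation is
  gradient-guided and the disturbance magnitude decays geometrically per
  mental exploration, so the gradient progressively dominates. A trial ends
  when the agent comes within the *crucial distance* (2 step lengths) of
  the target.

## Worked example

```
placenav run --out demo --seed 3
```

```
# session seed=3 sigma=4 -> demo/
trial  steps  optimality  siege
    1    382      34.727  0.799
    2     35       3.182  0.417
    3     20       1.818  0.238
    4     23       2.091  0.250
    5     21       1.909  0.409
    6     20       1.818  0.143
    7     15       1.364  0.062
    8     14       1.273  0.000
    9     11       1.000  0.167
   10     12       1.091  0.000
trials to optimal (ratio <= 1.5): 7
```

The first (random) search needs 382 steps to stumble onto the target at
(10, 10) from the entry at (1, 1). Nine mental explorations later the path
takes 11–12 steps — the geometric lower bound is 11 (straight-line distance
9 sqrt(2) minus the crucial distance 2) — so the final route is essentially
straight. `optimality` is steps divided by that bound; `siege` is the
fraction of revisited cells (1 - distinct cells / positions), 0 for a path
that never revisits a place field. The run directory contains per-trial
trajectory CSVs, the weight edge list, the strengthening-event log, a
summary JSON and a manifest whose seed reproduces the run byte for byte.

The variance study of the Gaussian width (wider fields escape the siege
regime and end with shorter paths):

```
placenav compare-variance --sigmas 3.52,4.00 --n-seeds 20 --seed 1
```

Library use mirrors the CLI:

```python
from placenav import ArenaConfig, run_session

session = run_session(ArenaConfig(seed=3))
print(session.steps_per_trial, session.trials_to_optimal)
```

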