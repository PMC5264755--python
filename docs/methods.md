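# Methods

## Model summary

The simulator couples three ingredients on a regular lattice of place
cells: a Gaussian firing-power kernel, a potentiation-only Hebbian rule on
directed synapses, and stochastic gradient navigation on the resulting
discrete energy field.

**Kernel.** The isolated firing power of a cell is a bivariate Gaussian
density of the animal's position about the place-field center, with axis
scales sigma1, sigma2. Two assumptions force this form: power factorises
over orthogonal axes, and depends only on distance from the center. The
test suite certifies both the closed form (peak value 1/(2 pi sigma1
sigma2), normalization to 1 over an 8-sigma domain) and the defining
functional equations of the log-kernel, h(x) + h(y) = h(sqrt(x^2 + y^2))
and h(r x) = r^2 h(x).

**Plasticity.** Whenever the nearest cell changes from j to i across one
step, omega_ji += eta * P_j * P_i, evaluated with the isolated powers at
the pre- and post-step positions. The time-windowed co-firing integral
behind this rule fixes neither its constant nor its window, so the
per-event product is the discrete surrogate; using isolated rather than
synaptically modulated powers keeps the increment bounded (a modulated
product makes the already non-convergent rule super-exponential). The rule
is LTP-only: weights never decrease, and nothing caps them. Both
properties are deliberate — the runaway is the mechanism behind the siege
phenomenon studied in the variance comparison. With
`high_power_radius > 0` the update generalises from the nearest-cell pair
to all ordered pairs of cells within that radius of the two positions,
weighted by their firing powers (the population form of the same rule);
the default is the nearest-cell pair only.

**Navigation field.** The composite field at step k assigns cell i at
center (x, y)

    P_k = (1 + sum_j omega_ji) * G(x, y; p_current) + [target known] * G(x, y; p_target).

Steering, however, differentiates the field *minus* the unit activity
packet, i.e. V_i = (sum_j omega_ji) * G + target term. Analytically the
packet's gradient vanishes at its own center, so it contributes nothing to
the navigation vector; on the lattice its finite-difference residue is of
order G * offset / sigma^2 — comparable to the far-field target pull — and
at edge cells the one-sided difference aims it into the boundary. Keeping
the packet in the differentiated field pins the agent at walls (the start
corner especially) and seeds spurious self-reinforcing traps; removing it
recovers the continuum gradient. The composite field itself is exposed and
tested unchanged.

**Gradient discretisation.** Central differences over the 4-neighbour
stencil with h = cell spacing, one-sided at lattice edges, evaluated at the
cell nearest the continuous position. Accuracy is O(h^2) against analytic
Gaussians (tested with an explicit third-derivative error bound).

**Trial protocol.** Trial 1 navigates by the disturbance alone (a uniform
random walk) until it first comes within the crucial distance of the
target, which activates the target term. Later trials are mental
explorations: gradient plus disturbance, weights updating throughout. The
disturbance direction is uniform on the circle; its magnitude is
`noise_magnitude` during random search and decays geometrically,
noise_magnitude * noise_decay^(t - 2), across mental explorations t =
2, 3, ... — the navigation vector's deterministic part thereby comes to
dominate as learning proceeds. Termination is strict (< crucial distance);
steps are clamped to the arena bounding box.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| grid_rows x grid_cols | 15 x 15 | cells | reference lattice (225 cells) |
| cell_spacing | 1 | length | lattice pitch; start (1,1), target (10,10) are lattice points |
| step_length | 1 | length | fixed stride of every step |
| crucial_distance | 2 | length | termination radius around the target |
| sigma1, sigma2 | 4.00 | length | kernel width; 3.52 is the narrow arm of the variance study |
| learning_increment (eta) | 10 | — | per-event Hebbian gain |
| noise_magnitude | 1e-3 | field units | initial disturbance magnitude |
| noise_decay | 0.75 | — | per-mental-exploration decay factor; 1.0 = fixed noise |
| initial_weight | 0 | — | weak symmetric baseline between neighbours |
| high_power_radius | 0 | length | 0 = nearest-cell firing; > 0 = population co-firing |
| max_steps_per_trial | 10000 | steps | safety cap; random searches median a few hundred steps |
| n_trials | 10 | — | one random search + nine mental explorations |

eta and the noise schedule are the two quantities the model does not pin
down from first principles; they were calibrated once, on probe seeds
disjoint from those used anywhere in the tests, to the regime the model is
meant to exhibit — a several-hundred-step first search collapsing to a
near-straight dozen-step route within ten trials — and then frozen. The
choices sit an order of magnitude below the instability boundary: at eta
roughly 30 and above, weight contrasts outgrow the escape forces within ten
trials and trajectories begin to stall (siege) even at sigma = 4. The
initial noise magnitude is of the order of the pre-learning gradient scale,
so the first mental explorations are genuinely stochastic. With these
defaults the 20-seed reference run gives a monotone median learning curve
(234 steps on trial 1 to 12 on trial 10, Spearman rho = -1.0), a median of
6 trials to reach 1.5x the geometric bound, and a clean variance contrast
(sigma 3.52 arm: median final steps 34.5 with stalled trials; sigma 4.00
arm: 12, none).

## Why the noise decays explicitly

The declining learning curve requires later mental explorations to be more
deterministic than earlier ones. One reading lets the fixed-magnitude
disturbance lose influence only because learning inflates the gradient.
Exploration of that reading across wide ranges of eta, noise magnitude,
firing-set radius and update gating shows it cannot produce the declining
curve here: the incoming-weight sums that modulate the field carry no
direction, so the learned landscape is attractor-like — any gain large
enough to steer first builds local maxima (concentrated around the start,
where every trial begins and lingers) that lengthen later trials and
ultimately trap them, while any smaller gain leaves trials 2..10
statistically flat. Letting the disturbance magnitude itself decay per
mental exploration — the enhancement of the deterministic part and the
decay of the stochastic part being two sides of the learning process —
yields the declining curve robustly while keeping the field and the
learning rule exactly as specified. `noise_decay = 1` restores the
fixed-noise variant for comparison.

## Synthetic conditions and what the tests show

All inputs are generated by the simulator itself; there is no external
data. The arena is a bare bounded square: no obstacles, walls (beyond the
clamped boundary), cue geometry, or multi-chart remapping. Place fields
are isotropic, identical, and noiseless; firing is a deterministic power
value rather than spikes. Passing tests therefore demonstrate properties
of the model — normalization, monotone potentiation, termination and
reproducibility contracts, the declining learning curve, the
variance/siege contrast — not claims about biological recordings.

## Numerical choices

- Nearest-cell ties (positions exactly halfway between centers) resolve to
  the lower cell id, making every trajectory deterministic given the seed.
- The normalization integral uses the trapezoid rule on a 1201^2 tensor
  grid over an 8-sigma square; with the integrand decayed to ~e^-32 at the
  edge the rule converges spectrally, far below the 1e-6 tolerance.
- All randomness flows through one `numpy.random.Generator` seeded from
  the config; a session is a pure function of its config.
- If the disturbance exactly cancels the gradient (measure-zero), the
  disturbance angle is redrawn; a zero gradient with zero noise raises an
  error rather than inventing a direction.
- Unterminated trials (step cap reached) are reported as such; a session
  aborts only if the *first* trial fails, since without target discovery
  the field's target term never activates.
- The strengthening-event log stores enough to recompute every increment
  (powers for pair events, positions for population events); replaying it
  from the initial state reproduces the weight matrix exactly and is
  tested as an oracle.

## Known limitations

- The potentiation-only rule diverges by design; sessions much longer than
  the ten-trial protocol will eventually siege at any gain.
- The geometric noise decay is a fixed schedule, not an emergent one; the
  decay constant is a modelling choice (0.75 per mental exploration).
- Boundary clamping shortens steps at walls, so step-length conservation
  holds only in the interior.
- trials_to_optimal uses a configurable 1.5x tolerance on the geometric
  lower bound; "optimal" is not otherwise defined by the model.
- The prior-model baseline of 15 trials enters only as a stored constant
  in the reduction metric; that model is not re-simulated.
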