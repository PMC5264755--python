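"""Single path-finding trials: random search, then gradient-guided steps.

Trial 1 is a completely random walk — the navigation vector is pure noise —
until the system comes within the crucial distance of the target (which
discovers the target and switches on its field term).  Every later trial is
mental exploration guided by the energy-field gradient: at each step the
field's steering part (synaptic modulation plus target term; the activity
packet's own gradient vanishes at its center) is rebuilt at the current
position, its discrete gradient is
taken at the nearest lattice cell, a random disturbance of uniformly
distributed direction is added, and the sum is normalised to a unit
direction vector

    n_{k+1} = (grad P_k + n_rand) / |grad P_k + n_rand|.

The system then advances one step length (clamped to the arena bounding
box).  Whenever the nearest cell changes across a step, the forward synapse
between the two cells is strengthened.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .arena import ArenaConfig, PlaceCellLattice, nearest_cell
from .energy_field import FieldParams, field_gradient, isolated_power, navigation_field
from .errors import UndefinedDirectionError
from .plasticity import WeightMatrix, associate_target, record_cofiring, record_transition

__all__ = ["Trajectory", "propose_direction", "advance_step", "run_trial"]


@dataclass
class Trajectory:
    """One trial's path with per-step navigation metadata.

    positions has n_steps + 1 rows (start included); directions, gradients
    and noise_draws have one row per step.  Gradients are zero on pure-random
    steps (trial 1 / target not yet discovered).
    """

    trial_index: int
    positions: np.ndarray = field(repr=False)
    directions: np.ndarray = field(repr=False)
    gradients: np.ndarray = field(repr=False)
    noise_draws: np.ndarray = field(repr=False)
    nearest_cells: np.ndarray = field(repr=False)
    terminated: bool = False

    @property
    def n_steps(self) -> int:
        return len(self.directions)


def _propose(gradient: np.ndarray, noise_magnitude: float,
             rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """(unit direction, noise draw) for one step; redraws on exact cancellation."""
    g = gradient
    if noise_magnitude == 0.0 and g[0] == 0.0 and g[1] == 0.0:
        raise UndefinedDirectionError("zero gradient with zero noise: direction undefined")
    while True:
        theta = rng.uniform(0.0, 2.0 * math.pi)
        n_rand = noise_magnitude * np.array([math.cos(theta), math.sin(theta)])
        v = g + n_rand
        norm = math.hypot(v[0], v[1])
        if norm > 0.0:
            return v / norm, n_rand
        if noise_magnitude == 0.0:
            raise UndefinedDirectionError("zero gradient with zero noise: direction undefined")


def propose_direction(gradient, noise_magnitude: float, rng: np.random.Generator) -> np.ndarray:
    """Unit navigation vector: gradient plus random disturbance, normalised.

    The disturbance has fixed magnitude ``noise_magnitude`` and direction
    theta ~ Uniform[0, 2 pi).  In the degenerate case where gradient and
    disturbance cancel exactly, theta is redrawn; with zero noise and zero
    gradient the direction is undefined and an error is raised.
    """
    direction, _ = _propose(np.asarray(gradient, dtype=float), noise_magnitude, rng)
    return direction


def advance_step(position, direction, step_length: float, bounds) -> np.ndarray:
    """One step of fixed length along ``direction``, clamped to the arena box."""
    (xlo, xhi), (ylo, yhi) = bounds
    x = position[0] + step_length * direction[0]
    y = position[1] + step_length * direction[1]
    return np.array([min(max(x, xlo), xhi), min(max(y, ylo), yhi)])


def run_trial(
    lattice: PlaceCellLattice,
    params: FieldParams,
    weights: WeightMatrix,
    config: ArenaConfig,
    trial_index: int,
    target_active: bool,
    rng: np.random.Generator,
) -> tuple[Trajectory, WeightMatrix, bool]:
    """Execute one path-finding trial from config.start.

    Returns the trajectory, the (mutated) weight matrix and the updated
    target-discovered flag.  Termination is strict: the trial ends when the
    distance to the target falls *below* the crucial distance.  Hitting
    max_steps_per_trial returns an unterminated trajectory, not an error.

    Gradient guidance starts with the first trial after target discovery;
    from then on the disturbance magnitude shrinks geometrically
    (``noise_magnitude * noise_decay ** (trial_index - 2)``), so navigation
    grows more deterministic as mental exploration repeats.
    """
    target = np.asarray(config.target, dtype=float)
    pos = np.asarray(config.start, dtype=float)
    bounds = config.bounds
    use_gradient = target_active and trial_index > 1 and config.gradient_navigation
    # The disturbance decays by a fixed factor per completed mental
    # exploration; purely random trials always use the full magnitude.
    noise = config.noise_magnitude
    if use_gradient:
        noise *= config.noise_decay ** max(0, trial_index - 2)

    positions = [pos.copy()]
    directions: list[np.ndarray] = []
    gradients: list[np.ndarray] = []
    noises: list[np.ndarray] = []
    cells = [nearest_cell(lattice, pos)]
    terminated = float(np.hypot(*(pos - target))) < config.crucial_distance

    step = 0
    while not terminated and step < config.max_steps_per_trial:
        if use_gradient:
            fld = navigation_field(
                lattice, params, weights, pos, target, target_active=True, step_index=step
            )
            grad = field_gradient(lattice, fld, cells[-1])
        else:
            grad = np.zeros(2)
        direction, n_rand = _propose(grad, noise, rng)
        noises.append(n_rand)
        new_pos = advance_step(pos, direction, config.step_length, bounds)
        new_cell = nearest_cell(lattice, new_pos)
        if new_cell != cells[-1]:
            _fire(lattice, params, weights, config, cells[-1], new_cell,
                  pos, new_pos, trial_index, step)
        directions.append(direction)
        gradients.append(grad)
        pos = new_pos
        positions.append(pos.copy())
        cells.append(new_cell)
        step += 1
        terminated = float(np.hypot(*(pos - target))) < config.crucial_distance

    if terminated:
        target_active = True
        final_cell = cells[-1]
        associate_target(
            weights,
            final_cell,
            isolated_power(params, lattice.center_of(final_cell), pos),
            isolated_power(params, target, pos),
            trial=trial_index,
            step=step,
        )

    traj = Trajectory(
        trial_index=trial_index,
        positions=np.array(positions),
        directions=np.array(directions).reshape(-1, 2),
        gradients=np.array(gradients).reshape(-1, 2),
        noise_draws=np.array(noises).reshape(-1, 2),
        nearest_cells=np.array(cells, dtype=int),
        terminated=bool(terminated),
    )
    return traj, weights, target_active


def _fire(lattice, params, weights, config, from_cell, to_cell, prev_pos, new_pos,
          trial_index, step) -> None:
    """Strengthen synapses for a nearest-cell change across one step.

    With high_power_radius = 0 (default) only the single nearest cell fires;
    a positive radius widens the firing set to every cell within that radius
    of the respective position.
    """
    r = config.high_power_radius
    if r <= 0:
        record_transition(
            weights, from_cell, to_cell,
            isolated_power(params, lattice.center_of(from_cell), prev_pos),
            isolated_power(params, lattice.center_of(to_cell), new_pos),
            trial=trial_index, step=step,
        )
        return
    record_cofiring(weights, lattice, params, prev_pos, new_pos, r,
                    trial=trial_index, step=step)
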