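"""Multi-trial sessions, learning-curve statistics and the variance study.

A session runs n_trials path-finding trials with one cumulatively updated
weight matrix: trial 1 is the completely random search that discovers the
target, later trials are gradient-guided mental explorations whose step
counts shrink as the learned synapses reshape the energy field.

Path efficiency is measured against the geometric lower bound

    minimal_steps = ceil((|start - target| - crucial_distance) / step_length)

(a trajectory cannot terminate in fewer steps, since each step shortens the
distance to the target by at most one step length).  A trial is "optimal"
when steps / minimal_steps <= a tolerance (default 1.5).  The variance study
runs paired-seed sessions at two Gaussian widths (3.52 and 4.00 by default):
the wider field tends to finish with shorter final paths, while the narrow
one is more prone to the siege failure mode in which runaway local weights
trap the path in a small region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .arena import ArenaConfig, PlaceCellLattice, build_arena
from .energy_field import FieldParams
from .errors import TargetNotFoundError, UndefinedOptimalityError
from .explorer import Trajectory, run_trial
from .plasticity import WeightMatrix, init_weights

__all__ = [
    "SessionResult",
    "ComparisonResult",
    "PRIOR_MODEL_TRIALS",
    "OPTIMALITY_TOLERANCE",
    "minimal_steps",
    "path_optimality",
    "run_session",
    "compare_variances",
    "siege_index",
    "learning_trend",
]

#: Trial count reported for the prior phase-coding comparison model; stored
#: constant used only for the relative-reduction metric, never re-simulated.
PRIOR_MODEL_TRIALS = 15

#: A trial counts as optimal when steps <= tolerance * geometric lower bound.
OPTIMALITY_TOLERANCE = 1.5


@dataclass
class SessionResult:
    """Per-trial records and statistics for one multi-trial session."""

    config: ArenaConfig
    trajectories: list[Trajectory] = field(repr=False)
    steps_per_trial: list[int]
    optimality_ratio: list[float]
    siege_indices: list[float]
    trials_to_optimal: int | None
    seed: int
    weights: WeightMatrix = field(repr=False, default=None)

    @property
    def final_steps(self) -> int:
        return self.steps_per_trial[-1]


@dataclass
class ComparisonResult:
    """Paired-seed sessions per Gaussian width plus summary medians."""

    sigmas: list[float]
    sessions: dict[float, list[SessionResult]] = field(repr=False)
    median_final_steps: dict[float, float]
    median_trials_to_optimal: dict[float, float]
    n_seeds: int
    ordering_confirmed: bool


def minimal_steps(config: ArenaConfig) -> int:
    """Geometric lower bound on the steps of any terminated trajectory."""
    d = math.hypot(config.start[0] - config.target[0], config.start[1] - config.target[1])
    return max(0, math.ceil((d - config.crucial_distance) / config.step_length))


def path_optimality(trajectory: Trajectory, config: ArenaConfig) -> float:
    """steps / minimal_steps for a terminated trajectory; always >= 1."""
    if not trajectory.terminated:
        raise UndefinedOptimalityError(
            f"trial {trajectory.trial_index} did not terminate; optimality undefined"
        )
    m = minimal_steps(config)
    if m == 0:
        return 1.0
    return trajectory.n_steps / m


def siege_index(trajectory: Trajectory, lattice: PlaceCellLattice) -> float:
    """Revisitation score in [0, 1): 1 - distinct cells visited / positions.

    0 means every position lay in a new place field; values near 1 mean the
    path was besieged in a handful of repeatedly visited cells.
    """
    n_positions = len(trajectory.nearest_cells)
    distinct = len(set(trajectory.nearest_cells.tolist()))
    return 1.0 - distinct / n_positions


def run_session(config: ArenaConfig, tolerance: float = OPTIMALITY_TOLERANCE) -> SessionResult:
    """Run config.n_trials sequential trials with shared, accumulating weights.

    Raises TargetNotFoundError if the first (random) trial exhausts
    max_steps_per_trial without discovering the target — without discovery
    the field's target term never switches on and learning cannot start.
    """
    lattice = build_arena(config)
    params = FieldParams.from_config(config)
    weights = init_weights(lattice, config.initial_weight, config.learning_increment)
    rng = np.random.default_rng(config.seed)

    target_active = False
    trajectories: list[Trajectory] = []
    for trial in range(1, config.n_trials + 1):
        traj, weights, target_active = run_trial(
            lattice, params, weights, config, trial, target_active, rng
        )
        if trial == 1 and not traj.terminated:
            raise TargetNotFoundError(
                f"first random trial hit max_steps_per_trial={config.max_steps_per_trial} "
                f"without coming within {config.crucial_distance} of the target; "
                "raise max_steps_per_trial or the crucial distance"
            )
        trajectories.append(traj)

    ratios = [
        path_optimality(t, config) if t.terminated else math.nan for t in trajectories
    ]
    sieges = [siege_index(t, lattice) for t in trajectories]
    to_opt = next(
        (t.trial_index for t, r in zip(trajectories, ratios)
         if t.terminated and r <= tolerance),
        None,
    )
    return SessionResult(
        config=config,
        trajectories=trajectories,
        steps_per_trial=[t.n_steps for t in trajectories],
        optimality_ratio=ratios,
        siege_indices=sieges,
        trials_to_optimal=to_opt,
        seed=config.seed,
        weights=weights,
    )


def compare_variances(
    base_config: ArenaConfig,
    sigmas: tuple[float, ...] = (3.52, 4.00),
    n_seeds: int = 20,
) -> ComparisonResult:
    """Paired-seed sessions per Gaussian width (both sigmas set equal).

    Seeds base_config.seed .. base_config.seed + n_seeds - 1 are shared
    across arms so each comparison is paired.  Reports per-arm medians of
    final-trial steps and trials-to-optimal, and whether the expected
    ordering (widest field -> fewest final steps) held for this run.
    """
    if len(sigmas) < 2:
        raise ValueError("compare_variances needs at least two sigma values")
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    sessions: dict[float, list[SessionResult]] = {}
    for s in sigmas:
        arm = []
        for k in range(n_seeds):
            cfg = replace(base_config, sigma1=s, sigma2=s, seed=base_config.seed + k)
            arm.append(run_session(cfg))
        sessions[s] = arm
    median_final = {
        s: float(np.median([r.final_steps for r in arm])) for s, arm in sessions.items()
    }
    median_to_opt = {
        s: float(np.median([
            r.trials_to_optimal if r.trials_to_optimal is not None else base_config.n_trials + 1
            for r in arm
        ]))
        for s, arm in sessions.items()
    }
    lo, hi = min(sigmas), max(sigmas)
    return ComparisonResult(
        sigmas=list(sigmas),
        sessions=sessions,
        median_final_steps=median_final,
        median_trials_to_optimal=median_to_opt,
        n_seeds=n_seeds,
        ordering_confirmed=bool(median_final[hi] <= median_final[lo]),
    )


def learning_trend(
    sessions: list[SessionResult], first_trial: int = 2
) -> tuple[float, float]:
    """Spearman correlation of median steps vs trial index across sessions.

    Trials before ``first_trial`` are excluded (trial 1 is the random search,
    not part of the learning curve).  Returns (rho, p_value); a negative rho
    is the declining learning trend.
    """
    n_trials = len(sessions[0].steps_per_trial)
    idx = np.arange(first_trial, n_trials + 1)
    medians = [
        float(np.median([s.steps_per_trial[t - 1] for s in sessions])) for t in idx
    ]
    rho, p = stats.spearmanr(idx, medians)
    return float(rho), float(p)
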