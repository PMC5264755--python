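"""Directed synaptic weights and the Hebbian energy learning rule.

Synapses between place cells are potentiation-only (LTP): when two cells
fire with high power one after another — operationally, when the nearest
cell to the system's position changes from j to i across a step — the
directed weight w_ji is strengthened once by

    dw = eta * P_j * P_i,

the product of the two cells' firing powers at the moments just before and
after the step, scaled by the learning increment eta.  The reverse weight
is untouched, so exploration writes asymmetric connections on top of the
weak symmetric baseline present before learning.  Cells co-firing with the
target cell additionally accumulate a target association w_ti (bookkeeping;
the navigation field represents target attraction by an additive Gaussian
instead, to avoid counting the target twice).

The rule has no decay and no cap: repeated traversal of one region can
inflate its weights without bound, which is what produces the model's
"siege" failure mode at small sigma.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .arena import PlaceCellLattice
from .errors import SelfSynapseError, WeightDomainError

__all__ = ["StrengtheningEvent", "CofiringEvent", "WeightMatrix", "init_weights",
           "record_transition", "record_cofiring", "associate_target", "replay_log"]


@dataclass(frozen=True)
class StrengtheningEvent:
    """One synaptic strengthening: enough to recompute dw independently."""

    trial: int
    step: int
    from_cell: int
    to_cell: int          # -1 marks a target association
    power_from: float
    power_to: float


@dataclass(frozen=True)
class CofiringEvent:
    """One population co-firing across a step (high_power_radius > 0 mode).

    Stores the two positions and the radius so the full increment block can
    be recomputed independently during replay.
    """

    trial: int
    step: int
    prev_pos: tuple[float, float]
    new_pos: tuple[float, float]
    radius: float


class WeightMatrix:
    """Directed synaptic strengths w_ji plus per-cell target associations.

    ``w[j, i]`` is the weight of the synapse from cell j to cell i. Weights
    never decrease.  Every strengthening is appended to ``event_log`` so the
    final matrix can be replayed exactly from the initial state.
    """

    def __init__(
        self,
        n_cells: int,
        learning_increment: float,
        initial_weight: float = 0.0,
        neighbor_pairs: Iterable[tuple[int, int]] = (),
    ) -> None:
        if learning_increment < 0:
            raise WeightDomainError(f"learning_increment must be >= 0, got {learning_increment!r}")
        if initial_weight < 0:
            raise WeightDomainError(f"initial_weight must be >= 0, got {initial_weight!r}")
        self.n_cells = n_cells
        self.learning_increment = float(learning_increment)
        self.initial_weight = float(initial_weight)
        self.w = np.zeros((n_cells, n_cells), dtype=float)
        for i, j in neighbor_pairs:
            self.w[i, j] = initial_weight
            self.w[j, i] = initial_weight
        self.target_assoc = np.zeros(n_cells, dtype=float)
        self.event_log: list[StrengtheningEvent] = []
        self._incoming = self.w.sum(axis=0)

    def incoming_sums(self) -> np.ndarray:
        """sum_j w_ji for every cell i (the synaptic gain of Eq-style 1+sum)."""
        return self._incoming

    def copy(self) -> "WeightMatrix":
        out = WeightMatrix(self.n_cells, self.learning_increment, self.initial_weight)
        out.w = self.w.copy()
        out.target_assoc = self.target_assoc.copy()
        out.event_log = list(self.event_log)
        out._incoming = self._incoming.copy()
        return out


def init_weights(
    lattice: PlaceCellLattice,
    initial_weight: float = 0.0,
    learning_increment: float = 0.0,
) -> WeightMatrix:
    """Weak symmetric baseline: every 4-neighbour pair gets w_ij = w_ji = w0."""
    pairs = [
        (i, j)
        for i in range(lattice.n_cells)
        for j in lattice.neighbors[i]
        if i < j
    ]
    return WeightMatrix(
        n_cells=lattice.n_cells,
        learning_increment=learning_increment,
        initial_weight=initial_weight,
        neighbor_pairs=pairs,
    )


def record_transition(
    weights: WeightMatrix,
    from_cell: int,
    to_cell: int,
    power_from: float,
    power_to: float,
    trial: int = 0,
    step: int = 0,
) -> WeightMatrix:
    """Strengthen the forward synapse after a j -> i firing succession.

    dw = eta * power_from * power_to is added to w[from, to] only; the
    reverse direction is untouched (asymmetric LTP).  Mutates and returns
    ``weights``.
    """
    if from_cell == to_cell:
        raise SelfSynapseError(f"cell {from_cell} cannot strengthen a synapse onto itself")
    if power_from < 0 or power_to < 0:
        raise WeightDomainError(
            f"powers must be >= 0, got {power_from!r}, {power_to!r}"
        )
    dw = weights.learning_increment * power_from * power_to
    weights.w[from_cell, to_cell] += dw
    weights._incoming[to_cell] += dw
    weights.event_log.append(
        StrengtheningEvent(trial, step, from_cell, to_cell, float(power_from), float(power_to))
    )
    return weights


def record_cofiring(
    weights: WeightMatrix,
    lattice: PlaceCellLattice,
    params,
    prev_pos,
    new_pos,
    radius: float,
    trial: int = 0,
    step: int = 0,
) -> WeightMatrix:
    """Strengthen all forward synapses between successively firing populations.

    Every cell within ``radius`` of the pre-step position fires, then every
    cell within ``radius`` of the post-step position; each ordered pair
    (j fired, then i) with j != i gains dw = eta * P_j(prev) * P_i(new),
    the Gaussian firing powers at the respective moments.  This is the
    population form of the succession rule: increments are spread over the
    whole co-active neighbourhood in proportion to firing power, instead of
    being lumped onto the single nearest-cell pair.
    """
    from .energy_field import _gaussian  # local import to avoid a cycle

    prev_pos = np.asarray(prev_pos, dtype=float)
    new_pos = np.asarray(new_pos, dtype=float)
    d_prev = np.hypot(*(lattice.centers - prev_pos).T)
    d_new = np.hypot(*(lattice.centers - new_pos).T)
    senders = np.flatnonzero(d_prev <= radius)
    receivers = np.flatnonzero(d_new <= radius)
    if senders.size and receivers.size:
        p_send = _gaussian(params, lattice.centers[senders], prev_pos)
        p_recv = _gaussian(params, lattice.centers[receivers], new_pos)
        block = weights.learning_increment * np.outer(p_send, p_recv)
        # j -> j pairs do not form synapses
        common = np.intersect1d(senders, receivers, assume_unique=True)
        js = np.searchsorted(senders, common)
        is_ = np.searchsorted(receivers, common)
        block[js, is_] = 0.0
        weights.w[np.ix_(senders, receivers)] += block
        weights._incoming[receivers] += block.sum(axis=0)
    weights.event_log.append(
        CofiringEvent(trial, step, (float(prev_pos[0]), float(prev_pos[1])),
                      (float(new_pos[0]), float(new_pos[1])), float(radius))
    )
    return weights


def associate_target(
    weights: WeightMatrix,
    cell: int,
    power_cell: float,
    power_target: float,
    trial: int = 0,
    step: int = 0,
) -> WeightMatrix:
    """Accumulate the cell <-> target co-firing association w_ti.

    Bookkeeping only: target attraction enters the navigation field as an
    additive Gaussian, not through this term.
    """
    if power_cell < 0 or power_target < 0:
        raise WeightDomainError(f"powers must be >= 0, got {power_cell!r}, {power_target!r}")
    weights.target_assoc[cell] += weights.learning_increment * power_cell * power_target
    weights.event_log.append(
        StrengtheningEvent(trial, step, cell, -1, float(power_cell), float(power_target))
    )
    return weights


def replay_log(
    lattice: PlaceCellLattice,
    initial_weight: float,
    learning_increment: float,
    events: Iterable[StrengtheningEvent | CofiringEvent],
    params=None,
) -> WeightMatrix:
    """Rebuild a weight matrix from scratch by replaying a strengthening log.

    Recomputes every dw from the logged powers (or, for population
    co-firing events, from the logged positions — ``params`` is required
    then), so a replayed matrix matching the live one certifies the update
    arithmetic end to end.
    """
    weights = init_weights(lattice, initial_weight, learning_increment)
    for ev in events:
        if isinstance(ev, CofiringEvent):
            if params is None:
                raise ValueError("replaying co-firing events requires field params")
            record_cofiring(weights, lattice, params, ev.prev_pos, ev.new_pos,
                            ev.radius, trial=ev.trial, step=ev.step)
        elif ev.to_cell == -1:
            associate_target(weights, ev.from_cell, ev.power_from, ev.power_to,
                             trial=ev.trial, step=ev.step)
        else:
            record_transition(weights, ev.from_cell, ev.to_cell,
                              ev.power_from, ev.power_to, trial=ev.trial, step=ev.step)
    return weights
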