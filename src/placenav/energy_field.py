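"""Firing power of place cells and the discrete neural energy field.

An isolated place cell fires with a power that falls off from its
place-field center as a 2-D Gaussian density

    P0(x, y) = 1/(2 pi sigma1 sigma2)
               * exp{-1/2 [((x-mu1)/sigma1)^2 + ((y-mu2)/sigma2)^2]},

the unique form compatible with two assumptions: the power factorises over
orthogonal axes, and it depends only on the distance from the center
(rotational symmetry).  Excitatory synapses scale this power by
(1 + w_ti + sum_j w_ji).

The *energy field* at navigation step k is the set of power values over all
place-field centers:

    P_k(x, y) = (1 + sum_{j != i} w_ji) * G(x, y; current position)
              + [target discovered] * G(x, y; target position),

where i is the cell centered at (x, y) and G is the Gaussian above.  The
field exists only at lattice centers — it is a discrete field — so its
gradient is estimated by finite differences over lattice neighbours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .arena import ArenaConfig, PlaceCellLattice
from .errors import NumericInputError, ShapeError, WeightDomainError

__all__ = [
    "FieldParams",
    "EnergyField",
    "isolated_power",
    "modulated_power",
    "composite_field",
    "field_gradient",
    "power_integral",
]


@dataclass(frozen=True)
class FieldParams:
    """Gaussian decay scales of the firing-power density.

    sigma1, sigma2 set how fast power decays away from the place-field
    center along x and y; the peak value is the density normalization
    1/(2 pi sigma1 sigma2) so the density integrates to 1 over the plane.
    """

    sigma1: float
    sigma2: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.sigma1) and self.sigma1 > 0):
            raise NumericInputError(f"sigma1 must be positive, got {self.sigma1!r}")
        if not (np.isfinite(self.sigma2) and self.sigma2 > 0):
            raise NumericInputError(f"sigma2 must be positive, got {self.sigma2!r}")

    @property
    def normalization(self) -> float:
        return 1.0 / (2.0 * math.pi * self.sigma1 * self.sigma2)

    @classmethod
    def from_config(cls, config: ArenaConfig) -> "FieldParams":
        return cls(sigma1=config.sigma1, sigma2=config.sigma2)


@dataclass(frozen=True)
class EnergyField:
    """Discrete energy field: one power value per place-field center."""

    values: np.ndarray = field(repr=False)
    source_position: tuple[float, float]
    target_position: tuple[float, float]
    step_index: int = 0


def _gaussian(params: FieldParams, centers: np.ndarray, position) -> np.ndarray:
    """Vectorised isolated power of cells at ``centers`` for one position."""
    dx = (position[0] - centers[..., 0]) / params.sigma1
    dy = (position[1] - centers[..., 1]) / params.sigma2
    return params.normalization * np.exp(-0.5 * (dx * dx + dy * dy))


def isolated_power(params: FieldParams, center, position) -> float:
    """Firing power of an isolated cell centered at ``center``.

    Strictly positive, maximal (= 1/(2 pi sigma1 sigma2)) when the system
    sits exactly at the place-field center.
    """
    c = np.asarray(center, dtype=float)
    p = np.asarray(position, dtype=float)
    if not (np.all(np.isfinite(c)) and np.all(np.isfinite(p))):
        raise NumericInputError(f"center/position must be finite, got {center!r}, {position!r}")
    return float(_gaussian(params, c, p))


def modulated_power(
    params: FieldParams,
    center,
    position,
    incoming_weight_sum: float,
    target_weight: float,
) -> float:
    """Synaptically modulated power: (1 + w_ti + sum_j w_ji) * isolated power."""
    if incoming_weight_sum < 0 or target_weight < 0:
        raise WeightDomainError(
            f"weights must be >= 0, got incoming_weight_sum={incoming_weight_sum!r}, "
            f"target_weight={target_weight!r}"
        )
    return (1.0 + target_weight + incoming_weight_sum) * isolated_power(params, center, position)


def composite_field(
    lattice: PlaceCellLattice,
    params: FieldParams,
    weights,
    current_position,
    target_position,
    target_active: bool,
    step_index: int = 0,
) -> EnergyField:
    """Energy field over all place-field centers for one navigation step.

    Each cell i at center (x, y) carries
    ``(1 + incoming weight sum of i) * G(x,y; current_position)``; once the
    target has been discovered a unit-weight Gaussian centered on the target
    is added.  The field is defined only at lattice centers.
    """
    incoming = weights.incoming_sums()
    if incoming.shape != (lattice.n_cells,):
        raise ShapeError(
            f"weight matrix dimensioned for {incoming.shape[0]} cells, "
            f"lattice has {lattice.n_cells}"
        )
    cur = np.asarray(current_position, dtype=float)
    tgt = np.asarray(target_position, dtype=float)
    if not (np.all(np.isfinite(cur)) and np.all(np.isfinite(tgt))):
        raise NumericInputError("positions must be finite")
    values = (1.0 + incoming) * _gaussian(params, lattice.centers, cur)
    if target_active:
        values = values + _gaussian(params, lattice.centers, tgt)
    return EnergyField(
        values=values,
        source_position=(float(cur[0]), float(cur[1])),
        target_position=(float(tgt[0]), float(tgt[1])),
        step_index=step_index,
    )


def navigation_field(
    lattice: PlaceCellLattice,
    params: FieldParams,
    weights,
    current_position,
    target_position,
    target_active: bool,
    step_index: int = 0,
) -> EnergyField:
    """Composite field minus the unit activity packet: the steering signal.

    The composite field's leading term is the Gaussian activity packet
    centered on the current position.  Analytically the packet's gradient
    vanishes at its own center, so it contributes nothing to the navigation
    vector; on the lattice, however, differencing the packet at the nearest
    cell leaves a residue of order G * offset / sigma^2 — as large as the
    far-field target pull — plus an inward bias at edge cells where only
    one-sided differences exist.  Steering therefore differentiates

        V_i = (incoming weight sum of i) * G(center_i; current position)
            + [target discovered] * G(center_i; target position),

    which is the composite field with the unit packet removed and equals
    grad P_k at the current position in the continuum limit.
    """
    incoming = weights.incoming_sums()
    if incoming.shape != (lattice.n_cells,):
        raise ShapeError(
            f"weight matrix dimensioned for {incoming.shape[0]} cells, "
            f"lattice has {lattice.n_cells}"
        )
    cur = np.asarray(current_position, dtype=float)
    tgt = np.asarray(target_position, dtype=float)
    values = incoming * _gaussian(params, lattice.centers, cur)
    if target_active:
        values = values + _gaussian(params, lattice.centers, tgt)
    return EnergyField(
        values=values,
        source_position=(float(cur[0]), float(cur[1])),
        target_position=(float(tgt[0]), float(tgt[1])),
        step_index=step_index,
    )


def field_gradient(lattice: PlaceCellLattice, field: EnergyField, at_cell: int) -> np.ndarray:
    """Discrete gradient (dP/dx, dP/dy) of the field at one lattice cell.

    Central differences over the 4-neighbour stencil with h = cell_spacing;
    one-sided differences at lattice edges where a neighbour is missing.
    """
    v = field.values
    if v.shape != (lattice.n_cells,):
        raise ShapeError(f"field has {v.shape[0]} values, lattice has {lattice.n_cells} cells")
    if not (0 <= at_cell < lattice.n_cells):
        raise IndexError(f"cell id {at_cell} out of range [0, {lattice.n_cells})")
    row, col = lattice.rowcol(at_cell)
    h = lattice.cell_spacing
    cols = lattice.grid_cols

    if 0 < col < cols - 1:
        gx = (v[at_cell + 1] - v[at_cell - 1]) / (2.0 * h)
    elif col == 0:
        gx = (v[at_cell + 1] - v[at_cell]) / h
    else:
        gx = (v[at_cell] - v[at_cell - 1]) / h

    if 0 < row < lattice.grid_rows - 1:
        gy = (v[at_cell + cols] - v[at_cell - cols]) / (2.0 * h)
    elif row == 0:
        gy = (v[at_cell + cols] - v[at_cell]) / h
    else:
        gy = (v[at_cell] - v[at_cell - cols]) / h
    return np.array([gx, gy], dtype=float)


def power_integral(
    params: FieldParams,
    center=(0.0, 0.0),
    half_width_sigmas: float = 8.0,
    n_points: int = 1201,
) -> float:
    """Numerically integrate the isolated-power density over a wide square.

    Trapezoidal rule on a tensor grid spanning ``half_width_sigmas`` times
    the larger sigma beyond the center in every direction.  Because the
    integrand decays to ~0 at the domain edge the trapezoid rule converges
    spectrally here; the default grid reaches well below 1e-10 error.
    Checks the normalization condition (integral = 1).
    """
    half = half_width_sigmas * max(params.sigma1, params.sigma2)
    xs = np.linspace(center[0] - half, center[0] + half, n_points)
    ys = np.linspace(center[1] - half, center[1] + half, n_points)
    grid = np.stack(np.meshgrid(xs, ys, indexing="ij"), axis=-1)
    # G(center; point) = G(point; center): evaluate the grid points as
    # "centers" against a fixed position to reuse the vectorised kernel.
    vals = _gaussian(params, grid, np.asarray(center, dtype=float))
    return float(np.trapezoid(np.trapezoid(vals, ys, axis=1), xs, axis=0))
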