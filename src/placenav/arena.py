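"""Place-cell lattice construction and position-to-cell lookup.

The model assumes a one-to-one correspondence between place cells and the
nodes of a regular rectangular lattice: each cell's place-field center sits
at a lattice node, and each cell is synaptically connected to its four
nearest neighbours.  Continuous 2-D positions are mapped to the cell whose
center is nearest (ties broken by lowest cell id, for determinism).

Lattice centers start at (1, 1) and advance by ``cell_spacing`` per row and
column, so with the default spacing of 1 the printed coordinates of the
reference setup — entry (1, 1), target (10, 10) on a 15x15 grid — are exact
lattice points.  Cell ids are row-major: ``id = row * grid_cols + col``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, NumericInputError

__all__ = ["ArenaConfig", "PlaceCellLattice", "build_arena", "nearest_cell"]

#: Lattice origin: the first place-field center sits at (1, 1).
ORIGIN = (1.0, 1.0)

#: Default learning increment eta (per-event Hebbian gain).  Calibrated once
#: so that synapses accumulate visibly over a ten-trial session while staying
#: below the runaway ("siege") regime of the non-convergent potentiation-only
#: rule; see docs/methods.md.
DEFAULT_LEARNING_INCREMENT = 10.0

#: Default initial magnitude of the random disturbance vector, of the order
#: of the energy-field gradient scale before learning; see docs/methods.md.
DEFAULT_NOISE_MAGNITUDE = 1e-3

#: Default per-mental-exploration decay factor of the disturbance magnitude
#: ("gradient navigation vector enhances and noise decays"); 1.0 disables
#: the decay.  See docs/methods.md.
DEFAULT_NOISE_DECAY = 0.75


@dataclass(frozen=True)
class ArenaConfig:
    """Full parameter set for one simulation; single source of truth.

    Defaults encode the reference setup: 225 (15 x 15) place cells with unit
    spacing, entry at (1, 1), target at (10, 10), step length 1, crucial
    (termination) distance 2, sigma1 = sigma2 = 4.00, ten trials.
    """

    grid_rows: int = 15
    grid_cols: int = 15
    cell_spacing: float = 1.0
    start: tuple[float, float] = (1.0, 1.0)
    target: tuple[float, float] = (10.0, 10.0)
    step_length: float = 1.0
    crucial_distance: float = 2.0
    sigma1: float = 4.0
    sigma2: float = 4.0
    learning_increment: float = DEFAULT_LEARNING_INCREMENT
    noise_magnitude: float = DEFAULT_NOISE_MAGNITUDE
    noise_decay: float = DEFAULT_NOISE_DECAY
    gradient_navigation: bool = True
    initial_weight: float = 0.0
    high_power_radius: float = 0.0
    max_steps_per_trial: int = 10_000
    n_trials: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("grid_rows", "grid_cols"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 2:
                raise ConfigurationError(f"{name} must be an integer >= 2, got {v!r}")
        for name in ("cell_spacing", "step_length", "crucial_distance", "sigma1", "sigma2"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ConfigurationError(f"{name} must be a positive finite length, got {v!r}")
        for name in ("learning_increment", "noise_magnitude", "initial_weight",
                     "high_power_radius"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ConfigurationError(f"{name} must be >= 0 and finite, got {v!r}")
        for name in ("max_steps_per_trial", "n_trials"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigurationError(f"{name} must be an integer >= 1, got {v!r}")
        if not (np.isfinite(self.noise_decay) and 0 < self.noise_decay <= 1):
            raise ConfigurationError(
                f"noise_decay must lie in (0, 1], got {self.noise_decay!r}"
            )
        if not isinstance(self.gradient_navigation, bool):
            raise ConfigurationError(
                f"gradient_navigation must be a boolean, got {self.gradient_navigation!r}"
            )
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigurationError(f"seed must be an integer, got {self.seed!r}")
        for name in ("start", "target"):
            p = getattr(self, name)
            if len(p) != 2 or not all(np.isfinite(c) for c in p):
                raise ConfigurationError(f"{name} must be a finite 2-D coordinate, got {p!r}")
            (xlo, xhi), (ylo, yhi) = self.bounds
            x, y = p
            if not (xlo <= x <= xhi and ylo <= y <= yhi):
                raise ConfigurationError(
                    f"{name}={p!r} lies outside the arena bounding box "
                    f"[{xlo},{xhi}] x [{ylo},{yhi}]"
                )

    @property
    def bounds(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """((xmin, xmax), (ymin, ymax)) spanned by the place-field centers."""
        x0, y0 = ORIGIN
        return (
            (x0, x0 + (self.grid_cols - 1) * self.cell_spacing),
            (y0, y0 + (self.grid_rows - 1) * self.cell_spacing),
        )


@dataclass(frozen=True)
class PlaceCellLattice:
    """Regular lattice of place-field centers with 4-neighbour adjacency."""

    grid_rows: int
    grid_cols: int
    cell_spacing: float
    centers: np.ndarray = field(repr=False)  # (n_cells, 2), row-major
    neighbors: tuple[tuple[int, ...], ...] = field(repr=False)

    @property
    def n_cells(self) -> int:
        return self.grid_rows * self.grid_cols

    def cell_id(self, row: int, col: int) -> int:
        return row * self.grid_cols + col

    def rowcol(self, cell: int) -> tuple[int, int]:
        return divmod(cell, self.grid_cols)

    def center_of(self, cell: int) -> np.ndarray:
        return self.centers[cell]


def build_arena(config: ArenaConfig) -> PlaceCellLattice:
    """Construct the place-cell lattice described by ``config``.

    Deterministic: identical configs yield identical lattices.  Centers are
    laid out row-major from the origin (1, 1); interior cells get 4
    neighbours, edge cells 3, corner cells 2.
    """
    rows, cols, s = config.grid_rows, config.grid_cols, config.cell_spacing
    x0, y0 = ORIGIN
    cc, rr = np.meshgrid(np.arange(cols), np.arange(rows))
    centers = np.column_stack(
        [x0 + cc.ravel() * s, y0 + rr.ravel() * s]
    ).astype(float)

    neighbors: list[tuple[int, ...]] = []
    for r in range(rows):
        for c in range(cols):
            nb = []
            if c > 0:
                nb.append(r * cols + c - 1)
            if c < cols - 1:
                nb.append(r * cols + c + 1)
            if r > 0:
                nb.append((r - 1) * cols + c)
            if r < rows - 1:
                nb.append((r + 1) * cols + c)
            neighbors.append(tuple(nb))
    return PlaceCellLattice(
        grid_rows=rows, grid_cols=cols, cell_spacing=s,
        centers=centers, neighbors=tuple(neighbors),
    )


def nearest_cell(lattice: PlaceCellLattice, position) -> int:
    """Cell id whose center is nearest to ``position`` (Euclidean).

    Exact halfway ties resolve to the lower cell id.  Positions outside the
    lattice map to the nearest boundary cell.
    """
    x, y = float(position[0]), float(position[1])
    if not (math.isfinite(x) and math.isfinite(y)):
        raise NumericInputError(f"position must be finite, got {position!r}")
    s = lattice.cell_spacing
    x0, y0 = ORIGIN
    # ceil(v - 1/2) is the nearest integer with halfway ties going DOWN,
    # i.e. to the lower row/col index and hence the lower cell id.
    col = math.ceil((x - x0) / s - 0.5)
    row = math.ceil((y - y0) / s - 0.5)
    col = min(max(col, 0), lattice.grid_cols - 1)
    row = min(max(row, 0), lattice.grid_rows - 1)
    return lattice.cell_id(row, col)
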