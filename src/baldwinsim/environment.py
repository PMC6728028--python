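"""Toroidal grid world with two seasonally cycling resource types.

The world is an ``m x m`` grid with continuous (toroidal) boundary
conditions.  Each cell is either empty or holds a stack of one of two
resource types (type 0 or type 1) with a positive integer quantity
``phi <= phi_max``.  The number of occupied food cells is held constant:
whenever cells are emptied by foraging, the same number of new food cells
is spawned at uniformly random empty positions at the end of the timestep.
Which type spawns is Bernoulli with the current season's type-0 proportion
``pi0``; seasons alternate every ``length`` timesteps.

Coordinates are 0-based ``(row, col)`` with row 0 at the "north" edge;
moving north decrements the row (with wraparound).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "SeasonSchedule",
    "Grid",
    "season_at",
    "move_position",
    "N_FEATURES",
    "N_FEATURES_TYPE_BLIND",
]


class ConfigurationError(ValueError):
    """Raised when a configuration value is structurally invalid."""


#: perception feature-vector lengths: 3x3 window, two type channels per cell
N_FEATURES = 18
#: type-blind variant: one "any food" channel per window cell
N_FEATURES_TYPE_BLIND = 9

# Window cell ordering is row-major over the 3x3 block centered on the agent
# (NW, N, NE, W, center, E, SW, S, SE); features are channel-minor, i.e.
# feature index = 2*cell + type  (or just cell, when type-blind).
_WINDOW_OFFSETS = np.array(
    [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)], dtype=np.int64
)

# direction index order matches learning.Action: north, south, east, west
_MOVE_DELTAS = {
    "north": (-1, 0),
    "south": (1, 0),
    "east": (0, 1),
    "west": (0, -1),
}

@dataclass(frozen=True)
class SeasonSchedule:
    """Two alternating seasons of fixed length.

    Parameters
    ----------
    length
        Timesteps per season (``l > 0``).
    pi0
        Per-season proportions of type-0 resources among newly spawned food,
        one value per season.  Equal values give a single-season (static)
        environment, used by the behavior-evaluation protocol.
    """

    length: int
    pi0: Tuple[float, float] = (0.9, 0.1)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ConfigurationError(f"season length must be positive, got {self.length}")
        if len(self.pi0) != 2 or not all(0.0 <= p <= 1.0 for p in self.pi0):
            raise ConfigurationError(f"season pi0 must be two values in [0, 1], got {self.pi0}")

    def season_index(self, t: int) -> int:
        if t < 0:
            raise ValueError("timestep must be nonnegative")
        return (t // self.length) % 2

    def at(self, t: int) -> Tuple[int, float]:
        """Return ``(season_index, pi0)`` governing timestep ``t``."""
        idx = self.season_index(t)
        return idx, self.pi0[idx]


def season_at(t: int, schedule: SeasonSchedule) -> Tuple[int, float]:
    """Season index and type-0 spawn proportion at timestep ``t``."""
    return schedule.at(t)


def move_position(pos: Tuple[int, int], direction: str, m: int) -> Tuple[int, int]:
    """One-cell move with toroidal wraparound.

    ``direction`` is one of ``"north"``, ``"south"``, ``"east"``, ``"west"``;
    north decrements the row.
    """
    dr, dc = _MOVE_DELTAS[direction]
    return ((pos[0] + dr) % m, (pos[1] + dc) % m)


class Grid:
    """Mutable grid state: per-cell resource type and quantity.

    ``rtype`` holds -1 for empty cells and the resource type (0/1) otherwise;
    ``qty`` holds the remaining quantity (0 for empty cells).  The set ``F``
    of food cells is exactly the set of positions with ``qty > 0``.
    """

    __slots__ = ("m", "n_food", "phi_max", "rtype", "qty", "_n_occupied")

    def __init__(self, m: int, n_food: int, phi_max: int = 5):
        if m <= 1:
            raise ConfigurationError(f"grid side length must exceed 1, got {m}")
        if not (0 < n_food < m * m):
            raise ConfigurationError(
                f"food-cell target must satisfy 0 < n_food < m^2 = {m * m}, got {n_food}"
            )
        if phi_max < 1:
            raise ConfigurationError(f"phi_max must be at least 1, got {phi_max}")
        self.m = int(m)
        self.n_food = int(n_food)
        self.phi_max = int(phi_max)
        self.rtype = np.full((m, m), -1, dtype=np.int8)
        self.qty = np.zeros((m, m), dtype=np.int32)
        self._n_occupied = 0

    # -- bookkeeping ---------------------------------------------------

    @property
    def n_food_cells(self) -> int:
        """Current |F| (maintained incrementally; equals ``(qty > 0).sum()``)."""
        return self._n_occupied

    def food_positions(self) -> np.ndarray:
        """``(|F|, 2)`` array of (row, col) positions currently holding food."""
        return np.argwhere(self.qty > 0)

    def to_frame(self) -> pd.DataFrame:
        """Snapshot of occupied cells as columns (row, col, type, quantity)."""
        pos = self.food_positions()
        return pd.DataFrame(
            {
                "row": pos[:, 0],
                "col": pos[:, 1],
                "type": self.rtype[pos[:, 0], pos[:, 1]].astype(int),
                "quantity": self.qty[pos[:, 0], pos[:, 1]].astype(int),
            }
        )

    # -- dynamics ------------------------------------------------------

    def respawn(self, pi0: float, rng: np.random.Generator) -> None:
        """Refill |F| to its configured constant.

        Each missing food cell is placed on a uniformly random empty cell;
        its type is 0 with probability ``pi0`` (else 1) and its quantity is
        uniform on ``{1, ..., phi_max}``.  Because ``n_food < m^2``, there
        are always at least ``deficit`` empty cells available.
        """
        deficit = self.n_food - self._n_occupied
        if deficit <= 0:
            return
        flat_empty = np.flatnonzero(self.qty.ravel() == 0)
        chosen = rng.choice(flat_empty, size=deficit, replace=False)
        rows, cols = np.unravel_index(chosen, (self.m, self.m))
        types = (rng.random(deficit) >= pi0).astype(np.int8)
        amounts = rng.integers(1, self.phi_max + 1, size=deficit, dtype=np.int32)
        self.rtype[rows, cols] = types
        self.qty[rows, cols] = amounts
        self._n_occupied = self.n_food

    def consume(self, pos: Tuple[int, int], whole_cell: bool = False) -> Optional[int]:
        """Take food from ``pos``; return the resource type, or None if empty.

        By default one unit is removed per call; ``whole_cell=True`` empties
        the cell in one action.  Cells reaching quantity 0 leave ``F`` (their
        type is reset to -1); respawning is a separate, end-of-step pass.
        """
        r, c = pos
        if self.qty[r, c] == 0:
            return None
        rt = int(self.rtype[r, c])
        if whole_cell:
            self.qty[r, c] = 0
        else:
            self.qty[r, c] -= 1
        if self.qty[r, c] == 0:
            self.rtype[r, c] = -1
            self._n_occupied -= 1
        return rt

    # -- perception ----------------------------------------------------

    def perceive(self, pos: Tuple[int, int], type_blind: bool = False) -> np.ndarray:
        """Binary perception features for the 3x3 window centered on ``pos``.

        Food presence only -- quantities are not exposed.  With two type
        channels the vector has length 18 (feature ``2*cell + type``); the
        type-blind variant collapses the channels to 9 "any food" features.
        """
        rows = np.array([pos[0]], dtype=np.int64)
        cols = np.array([pos[1]], dtype=np.int64)
        return self.perceive_many(rows, cols, type_blind=type_blind)[0]

    def perceive_many(
        self, rows: np.ndarray, cols: np.ndarray, type_blind: bool = False
    ) -> np.ndarray:
        """Vectorized :meth:`perceive` for ``n`` agents; returns ``(n, f)`` floats."""
        wr = (rows[:, None] + _WINDOW_OFFSETS[:, 0]) % self.m
        wc = (cols[:, None] + _WINDOW_OFFSETS[:, 1]) % self.m
        rt = self.rtype[wr, wc]  # (n, 9)
        if type_blind:
            return (rt >= 0).astype(np.float64)
        out = np.zeros((rows.shape[0], N_FEATURES), dtype=np.float64)
        out[:, 0::2] = rt == 0
        out[:, 1::2] = rt == 1
        return out
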