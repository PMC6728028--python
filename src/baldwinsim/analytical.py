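"""Closed-form plasticity-fitness landscape.

A reactive individual with skill ``s`` collects expected fitness

    W(s) = pi0 * s**q + (1 - pi0) * (1 - s)**q

over an environment offering resource 0 with proportion ``pi0``.  A plastic
individual with aptitude ``alpha`` can express any skill within ``delta``
of its aptitude, adopting the best reachable skill for each resource, at a
linear cost ``c * delta``:

    W(alpha, delta) = pi0 * min(1, alpha + delta)**q
                    + (1 - pi0) * min(1, 1 - alpha + delta)**q
                    - c * delta

``delta`` proxies learning speed relative to season length.  Scanning the
(aptitude, delta) lattice reveals the veering structure: for q > 1 and a
small positive cost, the per-delta optimal aptitudes start at the extremes
(0, 1) at delta = 0, move inward as the symmetric pair {delta, 1 - delta},
and merge into a unique generalist optimum alpha = 0.5 at delta = 0.5 —
a genotype that is never expressed as the plastic response.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "AnalyticParams",
    "skill_range",
    "reactive_fitness",
    "plastic_fitness",
    "Landscape",
    "fitness_landscape",
    "per_delta_optima",
    "OptimalConfiguration",
    "optimal_configuration",
    "critical_delta",
]

#: optima within this tolerance of the maximum are grouped as ties
TIE_TOL = 1e-9


@dataclass(frozen=True)
class AnalyticParams:
    """Regime of the closed-form landscape.

    q : skill-success exponent (> 0); q > 1 is the specialist-favoring
        regime of the main analysis.
    c : linear cost of plasticity per unit of delta (>= 0).
    pi0 : proportion of resource 0 (0.5 = symmetric seasons).
    grid_step : lattice resolution for aptitude and delta scans.
    """

    q: float = 2.0
    c: float = 0.1
    pi0: float = 0.5
    grid_step: float = 0.01

    def __post_init__(self) -> None:
        if self.q <= 0:
            raise ValueError(f"q must be positive, got {self.q}")
        if self.c < 0:
            raise ValueError(f"plasticity cost must be nonnegative, got {self.c}")
        if not 0.0 <= self.pi0 <= 1.0:
            raise ValueError(f"pi0 must be in [0, 1], got {self.pi0}")
        if not 0.0 < self.grid_step <= 0.5:
            raise ValueError(f"grid_step must be in (0, 0.5], got {self.grid_step}")

    def axis(self) -> np.ndarray:
        """Closed [0, 1] lattice including both endpoints."""
        n = int(round(1.0 / self.grid_step))
        return np.linspace(0.0, 1.0, n + 1)


def skill_range(alpha: float, delta: float) -> Tuple[float, float]:
    """Expressible skill interval ``(max(0, a - d), min(1, a + d))``."""
    if not (0.0 <= alpha <= 1.0 and 0.0 <= delta <= 1.0):
        raise ValueError("aptitude and delta must lie in [0, 1]")
    return (max(0.0, alpha - delta), min(1.0, alpha + delta))


def reactive_fitness(s, params: AnalyticParams):
    """Fitness of a non-plastic individual with fixed skill ``s``."""
    s = np.asarray(s, dtype=np.float64)
    out = params.pi0 * s**params.q + (1.0 - params.pi0) * (1.0 - s) ** params.q
    return float(out) if out.ndim == 0 else out


def plastic_fitness(alpha, delta, params: AnalyticParams):
    """Fitness of a plastic individual (best reachable skill per resource,
    minus the plasticity cost).  Reduces to :func:`reactive_fitness` at
    ``delta = 0``.  Broadcasts over array arguments."""
    alpha = np.asarray(alpha, dtype=np.float64)
    delta = np.asarray(delta, dtype=np.float64)
    s0 = np.minimum(1.0, alpha + delta)
    s1 = np.minimum(1.0, 1.0 - alpha + delta)
    out = (
        params.pi0 * s0**params.q
        + (1.0 - params.pi0) * s1**params.q
        - params.c * delta
    )
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class Landscape:
    """Fitness on the (delta, aptitude) lattice: ``values[i, j]`` is the
    fitness at ``deltas[i]``, ``alphas[j]``."""

    alphas: np.ndarray
    deltas: np.ndarray
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        d, a = np.meshgrid(self.deltas, self.alphas, indexing="ij")
        return pd.DataFrame(
            {"delta": d.ravel(), "aptitude": a.ravel(), "fitness": self.values.ravel()}
        )


def fitness_landscape(params: AnalyticParams) -> Landscape:
    """Plastic fitness at every (aptitude, delta) lattice point of [0, 1]^2."""
    axis = params.axis()
    values = plastic_fitness(axis[None, :], axis[:, None], params)
    return Landscape(alphas=axis, deltas=axis, values=values)


def per_delta_optima(
    landscape: Landscape, tol: float = TIE_TOL
) -> List[np.ndarray]:
    """For each delta row, the set of aptitudes within ``tol`` of the row
    maximum (ties are reported, never silently broken)."""
    out = []
    for row in landscape.values:
        out.append(landscape.alphas[row >= row.max() - tol])
    return out


@dataclass(frozen=True)
class OptimalConfiguration:
    """Global landscape optimum and the per-delta attractor structure.

    ``delta_star`` is the smallest delta achieving the global maximum
    (within tolerance); ``alpha_star`` the argmax-aptitude set at that
    delta.  ``per_delta_alpha`` lists the argmax-aptitude set for every
    scanned delta.
    """

    delta_star: float
    alpha_star: np.ndarray
    max_fitness: float
    deltas: np.ndarray
    per_delta_alpha: List[np.ndarray]


def optimal_configuration(
    params: AnalyticParams, tol: float = TIE_TOL
) -> OptimalConfiguration:
    """Scan the lattice for the global maximizer(s) of the plastic fitness."""
    land = fitness_landscape(params)
    best = land.values.max()
    optima = per_delta_optima(land, tol)
    row_max = land.values.max(axis=1)
    tied_deltas = np.flatnonzero(row_max >= best - tol)
    i_star = int(tied_deltas[0])
    return OptimalConfiguration(
        delta_star=float(land.deltas[i_star]),
        alpha_star=optima[i_star],
        max_fitness=float(best),
        deltas=land.deltas,
        per_delta_alpha=optima,
    )


def critical_delta(params: AnalyticParams, tol: float = TIE_TOL) -> Optional[float]:
    """Smallest scanned delta whose argmax-aptitude set contains the
    generalist value 0.5 and no extreme value (0 or 1).

    Returns None when the regime has no specialist-to-generalist
    transition: either the center is already optimal at delta = 0 (the
    q < 1 regime, where interior aptitudes always win) or no scanned delta
    satisfies the condition.
    """
    land = fitness_landscape(params)
    half_step = params.grid_step / 2.0
    for i, alpha_set in enumerate(per_delta_optima(land, tol)):
        has_center = bool(np.any(np.abs(alpha_set - 0.5) <= half_step))
        has_extreme = bool(np.any((alpha_set <= tol) | (alpha_set >= 1.0 - tol)))
        if has_center and not has_extreme:
            delta = float(land.deltas[i])
            return None if delta == 0.0 else delta
    return None
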