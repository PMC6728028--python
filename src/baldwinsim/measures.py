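"""Population-level observables of specialization.

* the aptitude (genotype) distribution per timestep, binned over [0, 1];
* the lifetime foraging-history distribution: per agent, the fraction of
  its successful forages that hit a given resource type;
* the L2 norm between two binned distributions;
* Shannon-based diet-diversity summaries: among-resource diversity (ARD,
  diversity of the population-pooled diet) and within-individual diversity
  (WID, mean diversity of individual diets);
* genetic-assimilation trajectories: ensemble-mean distance between the
  population's aptitudes and the season-favored target value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Sequence, Tuple

import numpy as np
from scipy.stats import entropy

__all__ = [
    "BinnedDistribution",
    "aptitude_histogram",
    "foraging_history_histogram",
    "l2_distance",
    "diet_diversity",
    "assimilation_trajectory",
]


@dataclass(frozen=True)
class BinnedDistribution:
    """Frequencies over K equal bins of [0, 1] (all-zero when empty)."""

    edges: np.ndarray
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        total = self.frequencies.sum()
        if self.frequencies.min(initial=0.0) < 0:
            raise ValueError("frequencies must be nonnegative")
        if total > 0 and abs(total - 1.0) > 1e-12:
            raise ValueError(f"frequencies must sum to 1 (or 0), got {total}")

    @property
    def k(self) -> int:
        return self.frequencies.shape[0]

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def _values_of(population) -> np.ndarray:
    """Accept an array of aptitudes or a sequence of agent objects."""
    if len(population) and hasattr(population[0], "genome"):
        return np.array([a.genome.aptitude for a in population], dtype=np.float64)
    return np.asarray(population, dtype=np.float64)


def _binned(values: np.ndarray, k: int) -> BinnedDistribution:
    edges = np.linspace(0.0, 1.0, k + 1)
    if values.size == 0:
        return BinnedDistribution(edges, np.zeros(k))
    counts, _ = np.histogram(values, bins=edges)
    return BinnedDistribution(edges, counts / values.size)


def aptitude_histogram(population, k: int = 20) -> BinnedDistribution:
    """Genotype distribution: aptitudes over K equal bins of [0, 1].

    ``population`` may be an array of aptitude values or a sequence of
    agents.  An empty population yields an all-zero distribution.
    """
    if k < 2:
        raise ValueError("need at least 2 bins")
    return _binned(_values_of(population), k)


def foraging_history_histogram(
    h0: np.ndarray, h1: np.ndarray, r: int = 0, k: int = 20
) -> Tuple[BinnedDistribution, int]:
    """Distribution of per-agent diet ratios ``H_r / (H_0 + H_1)``.

    Agents with no successful forages have an undefined ratio; they are
    excluded and their count returned alongside the histogram.
    """
    if k < 2:
        raise ValueError("need at least 2 bins")
    if r not in (0, 1):
        raise ValueError("resource type must be 0 or 1")
    h0 = np.asarray(h0, dtype=np.float64)
    h1 = np.asarray(h1, dtype=np.float64)
    total = h0 + h1
    ok = total > 0
    ratios = (h0 if r == 0 else h1)[ok] / total[ok]
    return _binned(ratios, k), int((~ok).sum())


def l2_distance(p: BinnedDistribution, q: BinnedDistribution) -> float:
    """Euclidean distance between two binned distributions on equal bins."""
    if p.k != q.k or not np.allclose(p.edges, q.edges):
        raise ValueError("distributions use different bins")
    return float(np.sqrt(((p.frequencies - q.frequencies) ** 2).sum()))


def diet_diversity(h0: np.ndarray, h1: np.ndarray) -> Tuple[float, float]:
    """Shannon diversity (natural log) of resource use: ``(ARD, WID)``.

    ARD pools successful forages across the whole population; WID is the
    mean of each forager's own two-category diet diversity (0 for a pure
    diet, ln 2 for an even one).  Agents without forages are excluded;
    if nobody foraged the measures are undefined and a ValueError is raised.
    """
    h0 = np.asarray(h0, dtype=np.float64)
    h1 = np.asarray(h1, dtype=np.float64)
    ok = (h0 + h1) > 0
    if not ok.any():
        raise ValueError("diet diversity undefined: no successful forages")
    ard = float(entropy([h0.sum(), h1.sum()]))
    wid = float(entropy(np.stack([h0[ok], h1[ok]]), axis=0).mean())
    return ard, wid


def assimilation_trajectory(
    logs: Sequence, target_fn: Callable[[int], float]
) -> Tuple[np.ndarray, np.ndarray]:
    """Ensemble-mean genetic-assimilation series.

    For each logged timestep, computes the population mean of
    ``|aptitude - target(season)|`` and averages it across runs (empty
    snapshots contribute NaN and are ignored in the mean).  Lower values
    mean the genotype sits closer to the season-favored configuration.
    Returns ``(times, distances)``.
    """
    if not logs:
        raise ValueError("need at least one trajectory log")
    times = logs[0].times
    for log in logs[1:]:
        if not np.array_equal(log.times, times):
            raise ValueError("logs were recorded on different timestep grids")
    dist = np.full((len(logs), times.size), np.nan)
    for i, log in enumerate(logs):
        for j, snap in enumerate(log.aptitudes):
            if snap.size:
                target = target_fn(int(log.seasons[j]))
                dist[i, j] = np.abs(snap - target).mean()
    with np.errstate(invalid="ignore"):
        series = np.nanmean(dist, axis=0)
    return times, series
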