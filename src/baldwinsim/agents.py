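"""Individual state, the genotype-to-phenotype map, and vital rates.

An agent's heritable genome holds a scalar *aptitude* in [0, 1] and the
initial Q-network parameters (weights and biases prior to any learning).
Aptitude sets the skill at birth; skill governs foraging success through
the specialization trade-off

    P_f(s, type 0) = s**q        P_f(s, type 1) = (1 - s)**q

so aptitude 1 is a type-0 specialist, aptitude 0 a type-1 specialist and
aptitude 0.5 a generalist.  Energy increases by ``epsilon`` per successful
forage; each timestep an agent reproduces with probability
``min(e / c_r, 1)`` and dies with probability ``min(age / c_d, 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Tuple

import numpy as np

from .learning import QNetwork

__all__ = [
    "AgentType",
    "Genome",
    "VitalRates",
    "AgentState",
    "ForageOutcome",
    "forage_success_prob",
    "attempt_forage",
    "cumulative_fitness",
    "reproduction_prob",
    "death_prob",
]


class AgentType(str, Enum):
    """Which traits are plastic during a lifetime.

    Reactive agents express their genome directly; ``learn_actions`` agents
    train the Q-network online; ``learn_actions_skill`` agents additionally
    shift their skill after successful forages.
    """

    REACTIVE = "reactive"
    LEARN_ACTIONS = "learn_actions"
    LEARN_ACTIONS_SKILL = "learn_actions_skill"

    @property
    def learns_actions(self) -> bool:
        return self is not AgentType.REACTIVE

    @property
    def learns_skill(self) -> bool:
        return self is AgentType.LEARN_ACTIONS_SKILL


@dataclass
class Genome:
    """Heritable configuration: aptitude plus initial network parameters."""

    aptitude: float
    weights: np.ndarray  # (5, n_features)
    biases: np.ndarray  # (5,)

    def __post_init__(self) -> None:
        if not 0.0 <= self.aptitude <= 1.0:
            raise ValueError(f"aptitude must lie in [0, 1], got {self.aptitude}")
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.biases = np.asarray(self.biases, dtype=np.float64)
        if not (np.isfinite(self.weights).all() and np.isfinite(self.biases).all()):
            raise ValueError("genome network parameters must be finite")

    def copy(self) -> "Genome":
        return Genome(self.aptitude, self.weights.copy(), self.biases.copy())


@dataclass(frozen=True)
class VitalRates:
    """Constants of the foraging/reproduction/death probabilities.

    q : skill-success exponent (> 0); q > 1 favors specialists.
    epsilon : energy gained per successful forage.
    c_r : reproduction normalization (probability e / c_r, capped at 1).
    c_d : death normalization (probability age / c_d, capped at 1).
    delta_s : skill increment per successful forage (0 disables).
    move_cost : energy cost of a movement action (0 by default).
    metabolic_cost : basal energy cost charged to every agent every
        timestep (energy is clamped at 0).  This is the upkeep that makes
        foraging success the binding constraint on reproduction; it also
        bounds the food-limited population size.
    """

    q: float = 2.0
    epsilon: float = 1.0
    c_r: float = 20.0
    c_d: float = 200.0
    delta_s: float = 0.05
    move_cost: float = 0.0
    metabolic_cost: float = 0.0

    def __post_init__(self) -> None:
        if self.q <= 0 or self.epsilon <= 0 or self.c_r <= 0 or self.c_d <= 0:
            raise ValueError("q, epsilon, c_r and c_d must all be positive")
        if self.delta_s < 0 or self.move_cost < 0 or self.metabolic_cost < 0:
            raise ValueError("delta_s, move_cost and metabolic_cost must be nonnegative")


@dataclass
class AgentState:
    """One individual: genome, plastic phenotype, energy, age, history."""

    id: int
    genome: Genome
    agent_type: AgentType
    skill: float
    energy: float
    position: Tuple[int, int]
    network: QNetwork
    age: int = 0
    forage_counts: np.ndarray = field(default_factory=lambda: np.zeros(2, dtype=np.int64))

    @classmethod
    def from_genome(
        cls,
        agent_id: int,
        genome: Genome,
        agent_type: AgentType,
        position: Tuple[int, int],
        energy: float,
        alpha_rl: float = 0.1,
        gamma: float = 0.9,
    ) -> "AgentState":
        """Newborn: skill from inherited aptitude, live network from genome."""
        net = QNetwork(genome.weights.copy(), genome.biases.copy(), alpha_rl, gamma)
        return cls(
            id=agent_id,
            genome=genome,
            agent_type=AgentType(agent_type),
            skill=genome.aptitude,
            energy=energy,
            position=position,
            network=net,
        )


class ForageOutcome(Enum):
    SUCCESS = "success"
    FAIL_EMPTY = "fail_empty"
    FAIL_ROLL = "fail_roll"


def forage_success_prob(s, r, q):
    """Probability of a successful forage: ``s**q`` for type 0, ``(1-s)**q``
    for type 1 (the complementarity trade-off).  Vectorizes over any argument.
    """
    s = np.asarray(s, dtype=np.float64)
    r = np.asarray(r)
    out = np.where(r == 0, s**q, (1.0 - s) ** q)
    return float(out) if out.ndim == 0 else out


def attempt_forage(
    agent: AgentState,
    grid,
    rates: VitalRates,
    rng: np.random.Generator,
    consume_whole_cell: bool = False,
):
    """Execute an eat action: returns ``(outcome, resource_type_or_None)``.

    Fails outright on an empty cell; otherwise succeeds with probability
    ``forage_success_prob(skill, type, q)``.  On success the cell is
    consumed, energy rises by ``epsilon`` and the matching history count
    increments; a failed roll changes nothing.
    """
    r, c = agent.position
    rt = int(grid.rtype[r, c])
    if rt < 0:
        return ForageOutcome.FAIL_EMPTY, None
    p = forage_success_prob(agent.skill, rt, rates.q)
    if rng.random() >= p:
        return ForageOutcome.FAIL_ROLL, rt
    grid.consume((r, c), whole_cell=consume_whole_cell)
    agent.energy += rates.epsilon
    agent.forage_counts[rt] += 1
    return ForageOutcome.SUCCESS, rt


def cumulative_fitness(agent: AgentState, epsilon: float) -> float:
    """Lifetime energy intake ``epsilon * (H_0 + H_1)`` (unaffected by
    reproduction splits)."""
    return float(epsilon * agent.forage_counts.sum())


def reproduction_prob(f: float, c_r: float) -> float:
    """``min(f / c_r, 1)`` for fitness energy ``f >= 0``."""
    return min(f / c_r, 1.0)


def death_prob(d: float, c_d: float) -> float:
    """``min(d / c_d, 1)`` for age ``d >= 0``: a linear age hazard."""
    return min(d / c_d, 1.0)
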