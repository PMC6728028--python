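"""Asexual reproduction with genome mutation and per-agent vital events.

Reproduction copies the parent's *genome* (not its learned phenotype),
perturbs aptitude and every network parameter with independent Gaussian
noise, and splits the parent's energy equally with the offspring.  Birth
and death are realized as independent per-agent Bernoulli trials each
timestep with the capped linear probabilities of the vital-rate model
("roulette wheel selection with stochastic acceptance"); no population-wide
normalization is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .agents import (
    AgentState,
    Genome,
    VitalRates,
    death_prob,
    reproduction_prob,
)

__all__ = ["MutationParams", "mutate_genome", "reproduce", "vital_events"]


@dataclass(frozen=True)
class MutationParams:
    """Mutation scales: Gaussian s.d. for aptitude (clamped to [0, 1])
    and for each network weight/bias."""

    sigma_alpha: float = 0.02
    sigma_w: float = 0.02

    def __post_init__(self) -> None:
        if self.sigma_alpha < 0 or self.sigma_w < 0:
            raise ValueError("mutation scales must be nonnegative")


def mutate_genome(g: Genome, params: MutationParams, rng: np.random.Generator) -> Genome:
    """Independent Gaussian perturbation of every gene; aptitude clamped."""
    aptitude = float(np.clip(g.aptitude + rng.normal(0.0, params.sigma_alpha), 0.0, 1.0))
    weights = g.weights + rng.normal(0.0, params.sigma_w, size=g.weights.shape)
    biases = g.biases + rng.normal(0.0, params.sigma_w, size=g.biases.shape)
    return Genome(aptitude, weights, biases)


def reproduce(
    parent: AgentState,
    params: MutationParams,
    rng: np.random.Generator,
    child_id: int,
) -> Tuple[AgentState, AgentState]:
    """Split the parent's energy and return ``(parent, offspring)``.

    The offspring genome is a mutated copy of the parent's *inherited*
    genome; its skill is its own aptitude and its live network is freshly
    initialized from its genome -- nothing learned by the parent leaks
    through (non-Lamarckian inheritance).  The offspring starts at the
    parent's cell with age 0 and an empty foraging history.
    """
    half = parent.energy / 2.0
    parent.energy = half
    child_genome = mutate_genome(parent.genome, params, rng)
    child = AgentState.from_genome(
        agent_id=child_id,
        genome=child_genome,
        agent_type=parent.agent_type,
        position=parent.position,
        energy=half,
        alpha_rl=parent.network.alpha,
        gamma=parent.network.gamma,
    )
    return parent, child


def vital_events(
    population: List[AgentState],
    rates: VitalRates,
    params: MutationParams,
    rng: np.random.Generator,
    next_id: int = 0,
    reproduction_on_cumulative_intake: bool = False,
) -> Tuple[List[AgentState], int, int, int]:
    """One timestep of births and deaths.

    Pre-existing agents are processed in a random permutation; each draws
    Bernoulli(P_r) (on success an offspring joins the population this
    timestep) and then Bernoulli(P_d) (on success the agent is removed).
    Newborns are not processed this timestep.  Returns
    ``(new_population, n_births, n_deaths, next_id)``.
    """
    survivors: List[AgentState] = []
    births: List[AgentState] = []
    order = rng.permutation(len(population))
    dead = np.zeros(len(population), dtype=bool)
    for i in order:
        agent = population[i]
        if reproduction_on_cumulative_intake:
            f = rates.epsilon * float(agent.forage_counts.sum())
        else:
            f = agent.energy
        if rng.random() < reproduction_prob(f, rates.c_r):
            _, child = reproduce(agent, params, rng, next_id)
            next_id += 1
            births.append(child)
        if rng.random() < death_prob(agent.age, rates.c_d):
            dead[i] = True
    survivors = [a for i, a in enumerate(population) if not dead[i]]
    return survivors + births, len(births), int(dead.sum()), next_id
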