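"""Simulation configuration: dataclasses, validation, YAML/JSON round trips.

A :class:`SimulationConfig` fully determines a run together with a seed.
Configuration files are plain YAML mappings mirroring the nested sections
(``grid``, ``seasons``, ``vital``, ``learning``, ``evolution``,
``perception`` plus top-level run keys); ``environment.consume_whole_cell``
is accepted as an alias for ``grid.consume_whole_cell``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Tuple, Union

import yaml

from .agents import AgentType, VitalRates
from .environment import (
    ConfigurationError,
    N_FEATURES,
    N_FEATURES_TYPE_BLIND,
    SeasonSchedule,
)
from .evolution import MutationParams

__all__ = [
    "GridConfig",
    "SeasonConfig",
    "VitalConfig",
    "LearningConfig",
    "EvolutionConfig",
    "PerceptionConfig",
    "SimulationConfig",
]


@dataclass(frozen=True)
class GridConfig:
    m: int = 30
    n_food_cells: int = 675
    phi_max: int = 1
    consume_whole_cell: bool = False

    def validate(self) -> None:
        if self.m <= 1:
            raise ConfigurationError(f"grid.m must exceed 1, got {self.m}")
        if not 0 < self.n_food_cells < self.m * self.m:
            raise ConfigurationError(
                f"grid.n_food_cells must be in (0, m^2), got {self.n_food_cells}"
            )
        if self.phi_max < 1:
            raise ConfigurationError(f"grid.phi_max must be >= 1, got {self.phi_max}")


@dataclass(frozen=True)
class SeasonConfig:
    length: int = 3000
    pi0: Tuple[float, float] = (1.0, 0.0)

    def validate(self) -> None:
        SeasonSchedule(self.length, tuple(self.pi0))  # reuses its checks

    def schedule(self) -> SeasonSchedule:
        return SeasonSchedule(self.length, tuple(self.pi0))


@dataclass(frozen=True)
class VitalConfig:
    q: float = 2.0
    epsilon: float = 1.0
    c_r: float = 1800.0
    c_d: float = 25000.0
    delta_s: float = 0.25
    move_cost: float = 0.0
    metabolic_cost: float = 0.0
    reproduction_on_cumulative_intake: bool = False

    def validate(self) -> None:
        self.rates()  # VitalRates enforces positivity

    def rates(self) -> VitalRates:
        return VitalRates(
            q=self.q,
            epsilon=self.epsilon,
            c_r=self.c_r,
            c_d=self.c_d,
            delta_s=self.delta_s,
            move_cost=self.move_cost,
            metabolic_cost=self.metabolic_cost,
        )


@dataclass(frozen=True)
class LearningConfig:
    alpha_rl: float = 0.1
    gamma: float = 0.9
    epsilon_explore: float = 0.05
    reward: float = 1.0
    init_weight_scale: float = 0.1

    def validate(self) -> None:
        if not 0.0 < self.alpha_rl <= 1.0:
            raise ConfigurationError(f"learning.alpha_rl must be in (0, 1], got {self.alpha_rl}")
        if not 0.0 <= self.gamma < 1.0:
            raise ConfigurationError(f"learning.gamma must be in [0, 1), got {self.gamma}")
        if not 0.0 <= self.epsilon_explore <= 1.0:
            raise ConfigurationError(
                f"learning.epsilon_explore must be in [0, 1], got {self.epsilon_explore}"
            )
        if self.init_weight_scale < 0:
            raise ConfigurationError("learning.init_weight_scale must be nonnegative")


@dataclass(frozen=True)
class EvolutionConfig:
    sigma_alpha: float = 0.02
    sigma_w: float = 0.02
    n_founders: int = 100
    founder_aptitude: float = 0.5
    founder_energy: float = 100.0

    def validate(self) -> None:
        MutationParams(self.sigma_alpha, self.sigma_w)
        if self.n_founders < 1:
            raise ConfigurationError("evolution.n_founders must be >= 1")
        if not 0.0 <= self.founder_aptitude <= 1.0:
            raise ConfigurationError("evolution.founder_aptitude must be in [0, 1]")
        if self.founder_energy < 0:
            raise ConfigurationError("evolution.founder_energy must be nonnegative")

    def mutation_params(self) -> MutationParams:
        return MutationParams(self.sigma_alpha, self.sigma_w)


@dataclass(frozen=True)
class PerceptionConfig:
    type_blind: bool = False


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of a run (plus ensemble/logging controls)."""

    grid: GridConfig = field(default_factory=GridConfig)
    seasons: SeasonConfig = field(default_factory=SeasonConfig)
    vital: VitalConfig = field(default_factory=VitalConfig)
    learning: LearningConfig = field(default_factory=LearningConfig)
    evolution: EvolutionConfig = field(default_factory=EvolutionConfig)
    perception: PerceptionConfig = field(default_factory=PerceptionConfig)
    agent_type: str = AgentType.LEARN_ACTIONS_SKILL.value
    L: int = 10_000
    n_runs: int = 1
    master_seed: int = 0
    log_every: int = 50
    record_deaths: bool = True
    disable_vital_events: bool = False

    def validate(self) -> "SimulationConfig":
        for section in (self.grid, self.seasons, self.vital, self.learning, self.evolution):
            section.validate()
        AgentType(self.agent_type)
        if self.L < 0:
            raise ConfigurationError(f"L must be nonnegative, got {self.L}")
        if self.n_runs < 1:
            raise ConfigurationError(f"n_runs must be >= 1, got {self.n_runs}")
        if self.log_every < 1:
            raise ConfigurationError(f"log_every must be >= 1, got {self.log_every}")
        return self

    @property
    def n_features(self) -> int:
        return N_FEATURES_TYPE_BLIND if self.perception.type_blind else N_FEATURES

    # -- serialization --------------------------------------------------

    def to_dict(self) -> Dict[str, Any]:
        d = dataclasses.asdict(self)
        d["seasons"]["pi0"] = list(self.seasons.pi0)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def replace(self, **overrides: Any) -> "SimulationConfig":
        """Shallow `dataclasses.replace`; nested sections must be passed whole."""
        return dataclasses.replace(self, **overrides)

    @classmethod
    def from_dict(cls, data: Dict[str, Any]) -> "SimulationConfig":
        data = dict(data)
        env = data.pop("environment", None)
        grid_data = dict(data.pop("grid", {}))
        if env and "consume_whole_cell" in env:
            grid_data.setdefault("consume_whole_cell", env["consume_whole_cell"])
        seasons = dict(data.pop("seasons", {}))
        if "pi0" in seasons:
            seasons["pi0"] = tuple(seasons["pi0"])
        cfg = cls(
            grid=GridConfig(**grid_data),
            seasons=SeasonConfig(**seasons),
            vital=VitalConfig(**data.pop("vital", {})),
            learning=LearningConfig(**data.pop("learning", {})),
            evolution=EvolutionConfig(**data.pop("evolution", {})),
            perception=PerceptionConfig(**data.pop("perception", {})),
            **data,
        )
        return cfg.validate()

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
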