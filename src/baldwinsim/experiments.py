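"""Preset protocols: the three study designs plus deterministic test fixtures.

* ``baldwin_effect`` — three arms (reactive, action-learning, action+skill
  learning) in a slowly cycling environment; compares the speed of genetic
  assimilation toward the season-favored specialist.
* ``veering`` — action+skill learners under long and short seasons plus a
  reactive short-season arm, all founded at aptitude 0.5; compares the
  final-epoch aptitude distributions (specialist split vs generalist center).
* ``behavior_eval`` — reactive, non-reproducing populations instantiated
  from evolved genomes and from two scripted baselines, foraging in a
  static half-and-half environment; compares lifetime diet distributions.

Runs are ensembles with per-arm paired seeds (run *i* of every arm shares a
seed), so arm contrasts can be evaluated per seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Dict, List, Optional, Tuple

import numpy as np

from .agents import AgentType, AgentState, Genome
from .config import (
    EvolutionConfig,
    GridConfig,
    SeasonConfig,
    SimulationConfig,
)
from .engine import Simulation, TrajectoryLog, ensemble_seeds
from .environment import Grid
from .learning import greedy_forager_network
from .measures import (
    assimilation_trajectory,
    diet_diversity,
    foraging_history_histogram,
    l2_distance,
)

__all__ = [
    "ExperimentSpec",
    "reduced_config",
    "baldwin_effect_spec",
    "veering_spec",
    "run_baldwin_effect",
    "run_veering",
    "run_behavior_eval",
    "make_fixture",
    "Fixture",
    "SHORT_SEASON",
    "LONG_SEASON",
]

#: season lengths (timesteps).  3000 is the printed season length; 200 is the
#: fast-cycling regime (a handful of generations per season).
SHORT_SEASON = 200
LONG_SEASON = 3000


@dataclass(frozen=True)
class ExperimentSpec:
    """A named protocol: a base config plus per-arm overrides."""

    name: str
    base: SimulationConfig
    variants: Dict[str, Dict[str, Any]]
    n_runs: int = 20
    master_seed: int = 0

    def arm_config(self, arm: str) -> SimulationConfig:
        cfg = self.base.replace(**self.variants[arm])
        return cfg.validate()


def reduced_config(**overrides: Any) -> SimulationConfig:
    """Desk-scale study conditions: 20x20 grid, 300 single-unit food
    cells (the same 75% cover as the full-scale default), 60 founders,
    20k steps."""
    base = SimulationConfig(
        grid=GridConfig(m=20, n_food_cells=300, phi_max=1),
        evolution=EvolutionConfig(n_founders=60),
        L=20_000,
        log_every=100,
        record_deaths=False,
    )
    return base.replace(**overrides).validate()


def baldwin_effect_spec(
    n_runs: int = 20, master_seed: int = 0, base: Optional[SimulationConfig] = None
) -> ExperimentSpec:
    """Three agent-type arms in the slowly cycling (long-season) environment;
    everything except the learned traits is identical across arms."""
    if base is None:
        base = reduced_config()
    base = base.replace(seasons=SeasonConfig(length=LONG_SEASON, pi0=base.seasons.pi0))
    variants = {
        "reactive": {"agent_type": AgentType.REACTIVE.value},
        "learn_actions": {"agent_type": AgentType.LEARN_ACTIONS.value},
        "learn_actions_skill": {"agent_type": AgentType.LEARN_ACTIONS_SKILL.value},
    }
    return ExperimentSpec("baldwin_effect", base, variants, n_runs, master_seed)


def veering_spec(
    n_runs: int = 20,
    master_seed: int = 0,
    base: Optional[SimulationConfig] = None,
    arms: Optional[List[str]] = None,
) -> ExperimentSpec:
    """Learning long/short season and reactive short season arms, founders
    at aptitude 0.5.  ``arms`` restricts the protocol to a subset."""
    if base is None:
        base = reduced_config()
    pi0 = base.seasons.pi0
    variants: Dict[str, Dict[str, Any]] = {
        "learning_long": {
            "agent_type": AgentType.LEARN_ACTIONS_SKILL.value,
            "seasons": SeasonConfig(length=LONG_SEASON, pi0=pi0),
        },
        "learning_short": {
            "agent_type": AgentType.LEARN_ACTIONS_SKILL.value,
            "seasons": SeasonConfig(length=SHORT_SEASON, pi0=pi0),
        },
        "reactive_short": {
            "agent_type": AgentType.REACTIVE.value,
            "seasons": SeasonConfig(length=SHORT_SEASON, pi0=pi0),
        },
    }
    if arms is not None:
        variants = {k: variants[k] for k in arms}
    return ExperimentSpec("veering", base, variants, n_runs, master_seed)


def _run_arms(spec: ExperimentSpec) -> Dict[str, List[TrajectoryLog]]:
    """Paired-seed ensembles: run i of every arm uses the same seed."""
    seeds = ensemble_seeds(spec.master_seed, spec.n_runs)
    out: Dict[str, List[TrajectoryLog]] = {}
    for arm in spec.variants:
        cfg = spec.arm_config(arm)
        logs = []
        for i, ss in enumerate(seeds):
            sim = Simulation(cfg, seed=ss)
            sim.seed = i
            logs.append(sim.run())
        out[arm] = logs
    return out


def _season_target(pi0: Tuple[float, float]):
    """Aptitude value matching the season-favored specialist: aptitude 1
    when resource 0 dominates the season, else 0."""

    def target(season: int) -> float:
        return 1.0 if pi0[season] >= 0.5 else 0.0

    return target


def run_baldwin_effect(spec: ExperimentSpec) -> Dict[str, Any]:
    """Assimilation trajectories per arm plus a speed-ordering summary.

    Assimilation speed is summarized per run by the mean distance to the
    season target over the first season (lower = faster); the report gives
    the fraction of paired seeds on which each learning arm beats / trails
    the reactive baseline.
    """
    logs_by_arm = _run_arms(spec)
    target = _season_target(spec.base.seasons.pi0)
    season_len = spec.base.seasons.length
    report: Dict[str, Any] = {
        "experiment": spec.name,
        "n_runs": spec.n_runs,
        "master_seed": spec.master_seed,
        "config": spec.base.to_dict(),
        "arms": {},
    }
    per_run_auc: Dict[str, np.ndarray] = {}
    for arm, logs in logs_by_arm.items():
        times, series = assimilation_trajectory(logs, target)
        first_season = times <= season_len
        aucs = []
        for log in logs:
            _, s = assimilation_trajectory([log], target)
            aucs.append(float(np.nanmean(s[first_season])))
        per_run_auc[arm] = np.array(aucs)
        report["arms"][arm] = {
            "times": times.tolist(),
            "assimilation": series.tolist(),
            "first_season_mean_distance": aucs,
            "extinct_runs": sum(log.extinct_at is not None for log in logs),
        }
    if {"reactive", "learn_actions", "learn_actions_skill"} <= per_run_auc.keys():
        re, la, ls = (
            per_run_auc["reactive"],
            per_run_auc["learn_actions"],
            per_run_auc["learn_actions_skill"],
        )
        report["ordering"] = {
            "frac_learn_actions_faster_than_reactive": float((la < re).mean()),
            "frac_learn_actions_skill_slower_than_reactive": float((ls > re).mean()),
            "mean_first_season_distance": {
                "reactive": float(re.mean()),
                "learn_actions": float(la.mean()),
                "learn_actions_skill": float(ls.mean()),
            },
        }
    report["_logs"] = logs_by_arm
    return report


def _hist_stats(freq: np.ndarray) -> Dict[str, Any]:
    k = freq.shape[0]
    centers = (np.arange(k) + 0.5) / k
    outer = max(1, k // 10)  # outer 10% of bins on each side
    central = (centers >= 0.35) & (centers <= 0.65)
    return {
        "frequencies": freq.tolist(),
        "modal_bin_center": float(centers[int(freq.argmax())]),
        "extreme_mass": float(freq[:outer].sum() + freq[-outer:].sum()),
        "central_mass": float(freq[central].sum()),
        "low_extreme_occupied": bool(freq[:outer].sum() > 0),
        "high_extreme_occupied": bool(freq[-outer:].sum() > 0),
    }


def run_veering(spec: ExperimentSpec, bins: int = 20) -> Dict[str, Any]:
    """Final-epoch aptitude histograms per arm with shape summaries.

    The final epoch is the last 1000 timesteps at the default L = 20 000,
    scaled proportionally (L/20) for other lengths.  The report keeps the
    final populations of every run (genomes) for the behavior-evaluation
    protocol under the ``"_final_populations"`` key.
    """
    logs_by_arm = _run_arms(spec)
    window = max(spec.base.log_every, spec.base.L // 20)
    report: Dict[str, Any] = {
        "experiment": spec.name,
        "n_runs": spec.n_runs,
        "master_seed": spec.master_seed,
        "window": window,
        "config": spec.base.to_dict(),
        "arms": {},
        "_final_populations": {},
        "_logs": logs_by_arm,
    }
    for arm, logs in logs_by_arm.items():
        surviving = [log for log in logs if log.extinct_at is None]
        per_run = np.stack(
            [log.final_window_hist(bins, window) for log in (surviving or logs)]
        )
        mean_hist = per_run.mean(axis=0)  # over persisting runs
        stats = _hist_stats(mean_hist)
        stats["per_run"] = [_hist_stats(h) for h in per_run]
        stats["extinct_runs"] = len(logs) - len(surviving)
        report["arms"][arm] = stats
        report["_final_populations"][arm] = [log.final for log in logs]
    return report


def _sample_pool(
    pools: List[Dict[str, np.ndarray]], n: int, rng: np.random.Generator
) -> Dict[str, np.ndarray]:
    """Sample genomes with replacement from the union of final populations."""
    aptitude = np.concatenate([p["aptitude"] for p in pools])
    g_W = np.concatenate([p["g_W"] for p in pools])
    g_b = np.concatenate([p["g_b"] for p in pools])
    if aptitude.size == 0:
        raise ValueError("evolved population pool is empty (all runs extinct)")
    idx = rng.integers(0, aptitude.shape[0], size=n)
    return {"aptitude": aptitude[idx], "g_W": g_W[idx], "g_b": g_b[idx]}


def _baseline_founders(
    kind: str, n: int, n_features: int
) -> Dict[str, np.ndarray]:
    W, b = greedy_forager_network(n_features)
    if kind == "generalist":
        aptitude = np.full(n, 0.5)
    elif kind == "specialist":
        aptitude = np.where(np.arange(n) < n // 2, 0.05, 0.95)
    else:
        raise ValueError(f"unknown baseline {kind!r}")
    return {
        "aptitude": aptitude,
        "g_W": np.broadcast_to(W, (n, *W.shape)).copy(),
        "g_b": np.broadcast_to(b, (n, *b.shape)).copy(),
    }


def run_behavior_eval(
    evolved: Optional[Dict[str, List[Dict[str, np.ndarray]]]],
    base: Optional[SimulationConfig] = None,
    n_agents: int = 150,
    eval_steps: int = 2000,
    master_seed: int = 0,
    bins: int = 20,
) -> Dict[str, Any]:
    """Behavioral comparison of evolved genomes against scripted baselines.

    All four populations are reactive and non-reproducing, foraging for
    ``eval_steps`` in a static environment with equal resource proportions.
    ``evolved`` maps ``"reactive_short"``/``"learning_short"`` to lists of
    final-population dicts (from :func:`run_veering`); evolved genomes are
    sampled with replacement across runs.  Reports the lifetime diet
    histograms, pairwise L2 norms and (ARD, WID) per population.
    """
    needed = ("reactive_short", "learning_short")
    if evolved is None or not all(k in evolved and evolved[k] for k in needed):
        raise ValueError(
            "behavior evaluation needs evolved final populations for arms "
            f"{needed}; run the veering experiment (run_veering) first"
        )
    if base is None:
        base = reduced_config()
    cfg = base.replace(
        agent_type=AgentType.REACTIVE.value,
        seasons=SeasonConfig(length=max(eval_steps, 1), pi0=(0.5, 0.5)),
        disable_vital_events=True,
        L=eval_steps,
        record_deaths=False,
    ).validate()
    rng = np.random.default_rng(np.random.SeedSequence(master_seed))
    founders = {
        "evolved_reactive": _sample_pool(evolved["reactive_short"], n_agents, rng),
        "evolved_learning": _sample_pool(evolved["learning_short"], n_agents, rng),
        "generalist_baseline": _baseline_founders("generalist", n_agents, cfg.n_features),
        "specialist_baseline": _baseline_founders("specialist", n_agents, cfg.n_features),
    }
    seeds = ensemble_seeds(master_seed + 1, len(founders))
    report: Dict[str, Any] = {
        "experiment": "behavior_eval",
        "eval_steps": eval_steps,
        "n_agents": n_agents,
        "master_seed": master_seed,
        "config": cfg.to_dict(),
        "populations": {},
    }
    hists = {}
    for (name, f), ss in zip(founders.items(), seeds):
        log = Simulation(cfg, seed=ss, founders=f).run()
        h0, h1 = log.final["H"][:, 0], log.final["H"][:, 1]
        hist, n_excluded = foraging_history_histogram(h0, h1, r=0, k=bins)
        ard, wid = diet_diversity(h0, h1)
        hists[name] = hist
        report["populations"][name] = {
            "foraging_history": hist.frequencies.tolist(),
            "excluded_no_forage": n_excluded,
            "ard": ard,
            "wid": wid,
        }
    names = list(hists)
    report["l2"] = {
        f"{a}|{b}": l2_distance(hists[a], hists[b])
        for i, a in enumerate(names)
        for b in names[i + 1 :]
    }
    return report


# -- deterministic fixtures for tests ---------------------------------------


@dataclass
class Fixture:
    """A tiny, fully determined scenario: config, a prepared grid and agents."""

    name: str
    config: SimulationConfig
    grid: Grid
    agents: List[AgentState]


_FIXTURE_NAMES = (
    "single_agent_food",
    "two_agent_competition",
    "all_type0",
    "checkerboard",
)


def make_fixture(name: str, seed: int = 0) -> Fixture:
    """Deterministic miniature scenarios for tests.

    ``single_agent_food`` — 5x5 grid, one agent standing on a type-0 cell.
    ``two_agent_competition`` — two agents sharing a single one-unit cell.
    ``all_type0`` — every food cell type 0 (degenerate proportions).
    ``checkerboard`` — alternating type-0/type-1 food cells.
    """
    if name not in _FIXTURE_NAMES:
        raise ValueError(
            f"unknown fixture {name!r}; available: {', '.join(_FIXTURE_NAMES)}"
        )
    rng = np.random.default_rng(seed)
    cfg = SimulationConfig(
        grid=GridConfig(m=5, n_food_cells=4, phi_max=3),
        seasons=SeasonConfig(length=10, pi0=(1.0, 0.0)),
        evolution=EvolutionConfig(n_founders=1, founder_energy=0.0),
        L=10,
        log_every=1,
    ).validate()

    def agent(aid: int, pos, aptitude=0.5) -> AgentState:
        genome = Genome(
            aptitude,
            rng.uniform(-0.1, 0.1, (5, cfg.n_features)),
            rng.uniform(-0.1, 0.1, 5),
        )
        return AgentState.from_genome(aid, genome, AgentType.REACTIVE, pos, energy=0.0)

    grid = Grid(cfg.grid.m, cfg.grid.n_food_cells, cfg.grid.phi_max)
    if name == "single_agent_food":
        grid.rtype[2, 2] = 0
        grid.qty[2, 2] = 2
        for r, c in ((0, 0), (0, 4), (4, 0)):
            grid.rtype[r, c] = 1
            grid.qty[r, c] = 1
        grid._n_occupied = 4
        agents = [agent(0, (2, 2))]
    elif name == "two_agent_competition":
        grid.rtype[1, 1] = 0
        grid.qty[1, 1] = 1
        for r, c in ((3, 3), (3, 4), (4, 4)):
            grid.rtype[r, c] = 1
            grid.qty[r, c] = 1
        grid._n_occupied = 4
        agents = [agent(0, (1, 1), aptitude=1.0), agent(1, (1, 1), aptitude=1.0)]
    elif name == "all_type0":
        for r, c in ((0, 1), (1, 3), (2, 0), (4, 2)):
            grid.rtype[r, c] = 0
            grid.qty[r, c] = int(rng.integers(1, cfg.grid.phi_max + 1))
        grid._n_occupied = 4
        agents = [agent(0, (2, 2))]
    else:  # checkerboard
        cells = [(0, 0), (0, 2), (2, 0), (2, 2)]
        for i, (r, c) in enumerate(cells):
            grid.rtype[r, c] = i % 2
            grid.qty[r, c] = 1
        grid._n_occupied = 4
        agents = [agent(0, (1, 1))]
    return Fixture(name=name, config=cfg, grid=grid, agents=agents)
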