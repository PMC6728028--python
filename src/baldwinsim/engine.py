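"""Time-step-driven scheduler: environment + agents + learning + evolution.

The population lives in capacity-managed struct-of-arrays storage; each
timestep the compiled action kernel (:mod:`baldwinsim._kernels`) processes
every alive agent strictly sequentially in a fresh random permutation:
perceive -> (TD update of the pending transition) -> select action ->
execute (move, or forage with depletion competition).  Vital events,
aging and food respawn follow in vectorized numpy:

1. action phase (sequential per agent, random order);
2. vital events: every pre-existing agent draws Bernoulli(P_r) — on
   success an offspring with a mutated genome joins the population and the
   parent's energy is split — then Bernoulli(P_d); newborns are not
   processed this timestep;
3. survivors age by one step;
4. food respawns to the configured |F| with the current season's type mix.

All randomness flows through a single ``numpy.random.Generator`` per run,
so a (config, seed) pair reproduces every logged number bit for bit.
Ensemble member seeds derive from the master seed via
``numpy.random.SeedSequence.spawn``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._kernels import act_phase
from .agents import AgentType
from .config import SimulationConfig
from .environment import Grid, SeasonSchedule
from .learning import N_ACTIONS

__all__ = [
    "Population",
    "Simulation",
    "TrajectoryLog",
    "run_simulation",
    "run_ensemble",
    "ensemble_seeds",
]

# (name, dtype, trailing shape); float32 for bulk parameter arrays
_FIELDS = [
    ("ids", np.int64, ()),
    ("aptitude", np.float64, ()),
    ("g_W", np.float32, (N_ACTIONS, None)),  # inherited initial weights
    ("g_b", np.float32, (N_ACTIONS,)),
    ("W", np.float32, (N_ACTIONS, None)),  # live (learned) network
    ("b", np.float32, (N_ACTIONS,)),
    ("skill", np.float64, ()),
    ("energy", np.float64, ()),
    ("age", np.int64, ()),
    ("row", np.int64, ()),
    ("col", np.int64, ()),
    ("H", np.int64, (2,)),
    ("birth_t", np.int64, ()),
    ("prev_idx", np.int8, (9,)),
    ("prev_cnt", np.int8, ()),
    ("prev_a", np.int8, ()),
    ("prev_r", np.float32, ()),
    ("has_prev", np.bool_, ()),
]


class Population:
    """Capacity-managed struct-of-arrays population.

    Alive agents occupy rows ``[0, n)``; removal is swap-remove (the freed
    slot is filled from the tail), so per-event cost is O(events) rather
    than O(population).  Row order therefore carries no meaning — the
    engine always processes agents in an explicit random permutation.
    """

    def __init__(self, n_features: int, capacity: int = 256):
        self.n_features = n_features
        self.n = 0
        self._cap = capacity
        for name, dtype, shape in _FIELDS:
            full = (capacity, *[s if s is not None else n_features for s in shape])
            setattr(self, name, np.zeros(full, dtype=dtype))

    def _grow(self, need: int) -> None:
        cap = self._cap
        while cap < need:
            cap *= 2
        if cap == self._cap:
            return
        for name, dtype, shape in _FIELDS:
            old = getattr(self, name)
            new = np.zeros((cap, *old.shape[1:]), dtype=dtype)
            new[: self.n] = old[: self.n]
            setattr(self, name, new)
        self._cap = cap

    def view(self, name: str) -> np.ndarray:
        return getattr(self, name)[: self.n]

    def remove(self, idx: np.ndarray) -> None:
        """Swap-remove the given (unique, sorted ascending) row indices."""
        k = idx.size
        if k == 0:
            return
        n_new = self.n - k
        is_dead = np.zeros(self.n, dtype=bool)
        is_dead[idx] = True
        src = np.flatnonzero(~is_dead[n_new:]) + n_new
        dst = idx[idx < n_new]
        if dst.size:
            for name, _, _ in _FIELDS:
                arr = getattr(self, name)
                arr[dst] = arr[src]
        self.n = n_new

    def append_rows(self, rows: Dict[str, np.ndarray]) -> None:
        nb_ = rows["ids"].shape[0]
        self._grow(self.n + nb_)
        sl = slice(self.n, self.n + nb_)
        for name, values in rows.items():
            getattr(self, name)[sl] = values
        self.n += nb_


@dataclass
class TrajectoryLog:
    """Per-logged-timestep records plus end-of-run snapshots.

    Aptitude/skill population snapshots are kept per logged step (float32)
    so histograms and assimilation distances can be recomputed at any
    binning.  ``death_records`` holds per-agent lifetime summaries when
    enabled; ``final`` snapshots the surviving population (genomes
    included) for downstream protocols.
    """

    config: SimulationConfig
    seed: int
    times: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    seasons: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    pop_size: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    mean_energy: np.ndarray = field(default_factory=lambda: np.zeros(0))
    births: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    deaths: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    aptitudes: List[np.ndarray] = field(default_factory=list)
    skills: List[np.ndarray] = field(default_factory=list)
    death_records: Optional[pd.DataFrame] = None
    final: Optional[Dict[str, np.ndarray]] = None
    extinct_at: Optional[int] = None

    def mean_aptitude(self) -> np.ndarray:
        return np.array([a.mean() if a.size else np.nan for a in self.aptitudes])

    def aptitude_hist_series(self, bins: int = 20) -> np.ndarray:
        """(n_logs, bins) frequencies over [0, 1]; zero rows when extinct."""
        return _hist_series(self.aptitudes, bins)

    def skill_hist_series(self, bins: int = 20) -> np.ndarray:
        return _hist_series(self.skills, bins)

    def final_window_hist(self, bins: int = 20, window: int = 1000) -> np.ndarray:
        """Mean aptitude histogram over the last ``window`` timesteps of the
        run (the final-epoch averaging used by the veering analysis)."""
        lo = self.times.max() - window if self.times.size else 0
        sel = np.flatnonzero(self.times >= lo)
        return self.aptitude_hist_series(bins)[sel].mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.times,
                "season": self.seasons,
                "pop_size": self.pop_size,
                "mean_energy": self.mean_energy,
                "births": self.births,
                "deaths": self.deaths,
                "mean_aptitude": self.mean_aptitude(),
                "mean_skill": np.array(
                    [s.mean() if s.size else np.nan for s in self.skills]
                ),
            }
        )

    def save(self, out_dir) -> None:
        """Write timestep CSV, per-agent lifetime CSV and JSON metadata."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out / "timesteps.csv", index=False)
        hists = self.aptitude_hist_series()
        pd.DataFrame(
            hists, columns=[f"bin_{i}" for i in range(hists.shape[1])]
        ).assign(t=self.times).to_csv(out / "aptitude_hist.csv", index=False)
        if self.death_records is not None:
            self.death_records.to_csv(out / "agents.csv", index=False)
        meta = {
            "seed": int(self.seed),
            "extinct_at": self.extinct_at,
            "config": self.config.to_dict(),
        }
        (out / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def _hist_series(snapshots: Sequence[np.ndarray], bins: int) -> np.ndarray:
    out = np.zeros((len(snapshots), bins))
    for i, snap in enumerate(snapshots):
        if snap.size:
            counts, _ = np.histogram(snap, bins=bins, range=(0.0, 1.0))
            out[i] = counts / snap.size
    return out


class Simulation:
    """A single seeded run; ``run()`` steps ``config.L`` times.

    ``founders`` optionally overrides the founder genomes with arrays
    (``aptitude`` (n,), ``g_W`` (n, 5, f), ``g_b`` (n, 5)), as used by the
    behavior-evaluation protocol.
    """

    def __init__(
        self,
        config: SimulationConfig,
        seed,
        founders: Optional[Dict[str, np.ndarray]] = None,
    ):
        self.config = config.validate()
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self.t = 0
        self.extinct_at: Optional[int] = None
        self.schedule: SeasonSchedule = config.seasons.schedule()
        self.rates = config.vital.rates()
        self.agent_type = AgentType(config.agent_type)
        self.n_features = config.n_features
        self.next_id = 0
        self._births_since_log = 0
        self._deaths_since_log = 0
        self._death_buf: List[np.ndarray] = []

        g = config.grid
        self.grid = Grid(g.m, g.n_food_cells, g.phi_max)
        self.grid.respawn(self.schedule.at(0)[1], self.rng)
        self.pop = self._make_founders(founders)

    def _make_founders(self, founders: Optional[Dict[str, np.ndarray]]) -> Population:
        cfg = self.config
        f = self.n_features
        if founders is None:
            n0 = cfg.evolution.n_founders
            aptitude = np.full(n0, cfg.evolution.founder_aptitude)
            scale = cfg.learning.init_weight_scale
            g_W = self.rng.uniform(-scale, scale, size=(n0, N_ACTIONS, f))
            g_b = self.rng.uniform(-scale, scale, size=(n0, N_ACTIONS))
        else:
            aptitude = np.asarray(founders["aptitude"], dtype=np.float64)
            g_W = np.asarray(founders["g_W"], dtype=np.float64)
            g_b = np.asarray(founders["g_b"], dtype=np.float64)
            n0 = aptitude.shape[0]
        pop = Population(f, capacity=max(256, 2 * n0))
        cells = self.rng.integers(0, cfg.grid.m, size=(n0, 2))
        pop.append_rows(
            {
                "ids": np.arange(n0, dtype=np.int64),
                "aptitude": aptitude,
                "g_W": g_W.astype(np.float32),
                "g_b": g_b.astype(np.float32),
                "W": g_W.astype(np.float32),
                "b": g_b.astype(np.float32),
                "skill": aptitude.copy(),
                "energy": np.full(n0, cfg.evolution.founder_energy),
                "age": np.zeros(n0, dtype=np.int64),
                "row": cells[:, 0],
                "col": cells[:, 1],
                "H": np.zeros((n0, 2), dtype=np.int64),
                "birth_t": np.zeros(n0, dtype=np.int64),
                "prev_idx": np.zeros((n0, 9), dtype=np.int8),
                "prev_cnt": np.zeros(n0, dtype=np.int8),
                "prev_a": np.zeros(n0, dtype=np.int8),
                "prev_r": np.zeros(n0, dtype=np.float32),
                "has_prev": np.zeros(n0, dtype=bool),
            }
        )
        self.next_id = n0
        return pop

    # -- stepping --------------------------------------------------------

    def step(self) -> None:
        cfg = self.config
        pop = self.pop
        n = pop.n
        if n > 0:
            rng = self.rng
            perm = rng.permutation(n)
            u_explore = rng.random(n)
            eat_rolls = rng.random(n)
            emptied = act_phase(
                self.grid.rtype,
                self.grid.qty,
                perm,
                pop.view("row"),
                pop.view("col"),
                pop.view("W"),
                pop.view("b"),
                pop.view("skill"),
                pop.view("energy"),
                pop.view("H"),
                pop.view("prev_idx"),
                pop.view("prev_cnt"),
                pop.view("prev_a"),
                pop.view("prev_r"),
                pop.view("has_prev"),
                u_explore,
                eat_rolls,
                self.agent_type.learns_actions,
                self.agent_type.learns_skill,
                cfg.perception.type_blind,
                cfg.learning.alpha_rl,
                cfg.learning.gamma,
                cfg.learning.epsilon_explore,
                cfg.learning.reward,
                self.rates.q,
                self.rates.epsilon,
                self.rates.delta_s,
                self.rates.move_cost,
                cfg.grid.consume_whole_cell,
            )
            self.grid._n_occupied -= int(emptied)
            if not cfg.disable_vital_events:
                self._vital_phase()  # ages survivors; newborns stay at age 0
            else:
                self.pop.view("age")[:] += 1
        _, pi0 = self.schedule.at(self.t)
        self.grid.respawn(pi0, self.rng)
        self.t += 1

    def _vital_phase(self) -> None:
        cfg = self.config
        pop = self.pop
        rng = self.rng
        rates = self.rates
        n = pop.n
        if rates.metabolic_cost > 0:
            e = pop.view("energy")
            np.maximum(e - rates.metabolic_cost, 0.0, out=e)
        if cfg.vital.reproduction_on_cumulative_intake:
            fitness = rates.epsilon * pop.view("H").sum(axis=1)
        else:
            fitness = pop.view("energy")
        reproducing = rng.random(n) < np.minimum(fitness / rates.c_r, 1.0)
        dying = rng.random(n) < np.minimum(pop.view("age") / rates.c_d, 1.0)

        parents = np.flatnonzero(reproducing)
        if parents.size:
            pop.view("energy")[parents] /= 2.0
            kids = self._offspring_rows(parents)
        dead = np.flatnonzero(dying)
        if dead.size:
            if cfg.record_deaths:
                self._death_buf.append(
                    np.column_stack(
                        [
                            pop.view("ids")[dead],
                            pop.view("age")[dead],
                            pop.view("H")[dead, 0],
                            pop.view("H")[dead, 1],
                            pop.view("skill")[dead],
                            pop.view("aptitude")[dead],
                        ]
                    ).astype(np.float64)
                )
            pop.remove(dead)
        pop.view("age")[:] += 1  # survivors age; newborns (appended next) stay 0
        if parents.size:
            pop.append_rows(kids)
        self._births_since_log += parents.size
        self._deaths_since_log += dead.size
        if pop.n == 0 and self.extinct_at is None:
            self.extinct_at = self.t + 1

    def _offspring_rows(self, parents: np.ndarray) -> Dict[str, np.ndarray]:
        """Mutated copies of the parents' genomes (heritable arrays only:
        nothing learned by the parent is inherited)."""
        cfg = self.config
        pop = self.pop
        rng = self.rng
        f = self.n_features
        nb_ = parents.shape[0]
        sa = cfg.evolution.sigma_alpha
        sw = cfg.evolution.sigma_w
        aptitude = np.clip(
            pop.view("aptitude")[parents] + rng.normal(0.0, sa, nb_), 0.0, 1.0
        )
        g_W = (
            pop.view("g_W")[parents].astype(np.float64)
            + rng.normal(0.0, sw, (nb_, N_ACTIONS, f))
        ).astype(np.float32)
        g_b = (
            pop.view("g_b")[parents].astype(np.float64)
            + rng.normal(0.0, sw, (nb_, N_ACTIONS))
        ).astype(np.float32)
        ids = np.arange(self.next_id, self.next_id + nb_, dtype=np.int64)
        self.next_id += nb_
        return {
            "ids": ids,
            "aptitude": aptitude,
            "g_W": g_W,
            "g_b": g_b,
            "W": g_W.copy(),
            "b": g_b.copy(),
            "skill": aptitude.copy(),
            "energy": pop.view("energy")[parents].copy(),  # already halved
            "age": np.zeros(nb_, dtype=np.int64),
            "row": pop.view("row")[parents].copy(),
            "col": pop.view("col")[parents].copy(),
            "H": np.zeros((nb_, 2), dtype=np.int64),
            "birth_t": np.full(nb_, self.t, dtype=np.int64),
            "prev_idx": np.zeros((nb_, 9), dtype=np.int8),
            "prev_cnt": np.zeros(nb_, dtype=np.int8),
            "prev_a": np.zeros(nb_, dtype=np.int8),
            "prev_r": np.zeros(nb_, dtype=np.float32),
            "has_prev": np.zeros(nb_, dtype=bool),
        }

    # -- run loop --------------------------------------------------------

    def run(self) -> TrajectoryLog:
        cfg = self.config
        log = TrajectoryLog(config=cfg, seed=self.seed if isinstance(self.seed, int) else -1)
        records: List[Tuple[int, int, int, float, int, int]] = []

        def record() -> None:
            pop = self.pop
            records.append(
                (
                    self.t,
                    self.schedule.season_index(self.t),
                    pop.n,
                    float(pop.view("energy").mean()) if pop.n else 0.0,
                    self._births_since_log,
                    self._deaths_since_log,
                )
            )
            log.aptitudes.append(pop.view("aptitude").astype(np.float32))
            log.skills.append(pop.view("skill").astype(np.float32))
            self._births_since_log = 0
            self._deaths_since_log = 0

        record()
        for _ in range(cfg.L):
            self.step()
            if self.t % cfg.log_every == 0 or self.t == cfg.L:
                record()

        arr = np.array(records, dtype=np.float64)
        log.times = arr[:, 0].astype(np.int64)
        log.seasons = arr[:, 1].astype(np.int64)
        log.pop_size = arr[:, 2].astype(np.int64)
        log.mean_energy = arr[:, 3]
        log.births = arr[:, 4].astype(np.int64)
        log.deaths = arr[:, 5].astype(np.int64)
        log.extinct_at = self.extinct_at
        if cfg.record_deaths:
            data = (
                np.concatenate(self._death_buf, axis=0)
                if self._death_buf
                else np.zeros((0, 6))
            )
            log.death_records = pd.DataFrame(
                data, columns=["id", "lifespan", "h0", "h1", "final_skill", "aptitude"]
            )
        pop = self.pop
        log.final = {
            "aptitude": pop.view("aptitude").copy(),
            "skill": pop.view("skill").copy(),
            "g_W": pop.view("g_W").copy(),
            "g_b": pop.view("g_b").copy(),
            "W": pop.view("W").copy(),
            "b": pop.view("b").copy(),
            "H": pop.view("H").copy(),
            "age": pop.view("age").copy(),
            "energy": pop.view("energy").copy(),
        }
        return log


def run_simulation(
    config: SimulationConfig,
    seed,
    founders: Optional[Dict[str, np.ndarray]] = None,
) -> TrajectoryLog:
    """Run ``config.L`` steps from a fresh state and return the log."""
    return Simulation(config, seed, founders=founders).run()


def ensemble_seeds(master_seed: int, n_runs: int) -> List[np.random.SeedSequence]:
    """Deterministic per-run seed sequences spawned from the master seed."""
    return np.random.SeedSequence(master_seed).spawn(n_runs)


def run_ensemble(
    config: SimulationConfig,
    n_runs: Optional[int] = None,
    master_seed: Optional[int] = None,
    founders: Optional[Dict[str, np.ndarray]] = None,
) -> List[TrajectoryLog]:
    """Independent Monte Carlo runs with seeds spawned from the master seed."""
    n = config.n_runs if n_runs is None else n_runs
    ms = config.master_seed if master_seed is None else master_seed
    logs = []
    for i, ss in enumerate(ensemble_seeds(ms, n)):
        sim = Simulation(config, seed=ss, founders=founders)
        log = sim.run()
        log.seed = i  # run index; the SeedSequence child drives the stream
        logs.append(log)
    return logs
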