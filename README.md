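# baldwinsim

An eco-evolutionary simulator and analytical toolkit for studying how
within-lifetime learning changes the course of genetic evolution — both its
**speed** (the Baldwin effect: learning accelerates or delays genetic
assimilation of a trait) and its **direction** (the Baldwin *veering*
effect: under fast environmental cycling, learners evolve a generalist
genotype that is never expressed as the learned phenotype).

It is aimed at researchers in evolutionary biology and artificial life who
want a small, fully reproducible model of plasticity–evolution interaction
that can be probed on a laptop.

## The model in brief

Agents forage on an `m x m` toroidal grid holding two resource types whose
availability alternates between two seasons.  Each agent carries a
heritable *aptitude* gene `α ∈ [0, 1]` that sets its initial *skill* `s`,
and heritable initial weights of a linear action-value network over its
3×3 perception.  Skill imposes a specialization trade-off on foraging
success:

    P_f(s, type 0) = s^q        P_f(s, type 1) = (1 − s)^q

Energy from successful forages drives reproduction, `P_r = min(e/c_r, 1)`
(asexual, energy split with a mutated offspring); death is an age hazard,
`P_d = min(d/c_d, 1)`.  Learning agents train the network online with the
one-step temporal-difference rule

    ΔQ = r + γ·max_a Q(I', a) − Q(I, a_prev),     Q ← Q + α_rl·ΔQ

using successful forages as the reward, and (optionally) shift their skill
by ΔS toward each successfully foraged type.  Reactive agents express
their genome unchanged.

The companion analytical model assigns a plastic individual with aptitude
`α` and plasticity range `δ` the fitness

    W(α, δ) = π₀·min(1, α+δ)^q + (1−π₀)·min(1, 1−α+δ)^q − c·δ

whose per-δ optima move from the specialist extremes `{0, 1}` at `δ = 0`
through the pair `{δ, 1−δ}` to a unique generalist optimum `α = 0.5` at
`δ = 0.5` — the attractor of the veering effect.

## Worked example

Evolve action+skill learners through 25 short seasons:

```python
from baldwinsim import SimulationConfig, run_simulation
from baldwinsim.config import GridConfig, SeasonConfig, EvolutionConfig

cfg = SimulationConfig(
    grid=GridConfig(m=20, n_food_cells=300, phi_max=1),
    seasons=SeasonConfig(length=200, pi0=(1.0, 0.0)),   # total seasonal switch
    evolution=EvolutionConfig(n_founders=60),
    agent_type="learn_actions_skill",
    L=5000, log_every=100, record_deaths=False,
)
log = run_simulation(cfg, seed=42)
print(log.to_frame().iloc[[0, 10, 25, 50]]
      [["t", "season", "pop_size", "mean_aptitude", "mean_skill"]])
print(log.final_window_hist(bins=5, window=500))
```

```
   t  season  pop_size  mean_aptitude  mean_skill
   0       0        60       0.500000    0.500000
1000       1      6107       0.499321    0.671040
2500       0      5815       0.498108    0.567177
5000       1      5758       0.501618    0.700644
[0.007, 0.181, 0.632, 0.177, 0.003]
```

The mean *skill* swings with the seasons (the learned, plastic response is
a specialist for whichever resource is in season) while the mean
*aptitude* stays pinned at 0.5 and its distribution concentrates in the
central bins — the genotype converges to a generalist configuration that
the phenotype never expresses.  That is the veering signature; a reactive
population under identical conditions instead splits into two specialist
morphs at the extremes (`baldwinsim experiment veering --out DIR` runs the
full contrast).

The analytical counterpart, from the CLI:

```
$ baldwinsim optimum --q 2 --c 0.1 --pi0 0.5 --step 0.01
{
  "delta_star": 0.5,
  "alpha_star": [0.5],
  "max_fitness": 0.95,
  "critical_delta": 0.5,
  ...
}
```

The landscape's global maximum sits at plasticity `δ* = 0.5` with the
unique optimal aptitude `0.5` (fitness `1 − c·δ = 0.95`), and `δ = 0.5` is
the smallest plasticity at which the optimal genotype is the generalist.

Other entry points: `baldwinsim simulate / ensemble` (seeded runs with CSV
and JSON logs), `baldwinsim landscape` (fitness lattice as CSV),
`baldwinsim experiment baldwin|veering|behavior` (the preset protocols).
See `docs/methods.md` for the model's assumptions, the reasoning behind
the default constants, and the protocol definitions.

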