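# Methods

`baldwinsim` couples three models: a spatial foraging ecology, a
within-lifetime learning model, and an evolutionary process — plus a
closed-form fitness analysis that predicts the evolutionary attractors of
the coupled system.

## The simulation model

### Environment

The world is an `m x m` torus.  Each cell is empty or holds one of two
resource types with an integer quantity `phi <= phi_max`.  The number of
occupied food cells `|F|` is a hard invariant: at the end of every
timestep, one new food item is spawned on a uniformly random empty cell
for every cell emptied during the step.  Spawned quantities are uniform on
`{1, ..., phi_max}`; the spawned type is 0 with probability `pi0` of the
current season.  Seasons alternate every `l` timesteps; with the default
proportions `(1, 0)` a season makes exactly one resource type available,
so the seasonal cycle fully inverts the reward structure of the world.

We deliberately default to *total* seasonal switching.  With partial
proportions (for instance 0.9/0.1), each specialist morph retains
exclusive access to its own type's spawn flux in its bad season; this
frequency-dependent niche partitioning stabilizes a bimodal specialist
polymorphism in every condition and masks the learning-driven effects the
package exists to study.  With a total switch, a wrong-season specialist
has no private channel, matching the complementary-proportion bookkeeping
of the analytical model.

### Agents, skill and vital rates

An agent's heritable genome is a scalar *aptitude* `alpha in [0, 1]` plus
the initial weights and biases of its action network.  The phenotypic
*skill* `s` starts at `alpha` at birth and controls foraging through the
specialization trade-off `P_f = s^q` (type 0) and `(1 - s)^q` (type 1);
the default `q = 2` makes this trade-off convex, so pure specialists beat
fixed generalists on expected success.  A successful forage yields
`epsilon` energy, one history increment and (for skill-learning agents) a
skill shift of `delta_s` toward the successful type.

Each timestep every agent reproduces with probability `min(e / c_r, 1)`
(energy split equally with the mutated offspring) and dies with
probability `min(age / c_d, 1)`, realized as independent per-agent
Bernoulli draws (stochastic acceptance).  Offspring inherit the genome
only — never the learned skill or the learned network (no Lamarckian
leak), start at the parent's cell with age 0, and are not processed in
their birth step.

### Learning

Action selection is epsilon-greedy over a linear action-value function
`Q(I) = W I + beta` on an 18-bit perception of the 3x3 neighborhood (two
type channels per cell; presence only, quantities are invisible).  The
network trains online with the one-step temporal-difference rule; the
reward is 1 exactly on successful forages.  Reactive agents freeze both
network and skill at their genomic values; `learn_actions` agents train
the network only; `learn_actions_skill` agents train both.

### Scheduling and reproducibility

Within a timestep, agents act strictly sequentially in a fresh random
permutation — each perceives the grid as left by the agents before it, so
depletion competition is exact — followed by vectorized vital events,
aging of survivors, and respawn.  The action phase is compiled (numba)
with float32 network arithmetic; the reference implementations in
`baldwinsim.learning` are float64 and define the semantics (an engine test
pins the compiled path to `td_update` on a controlled scenario).  Exact
Q-ties resolve to the lowest action index in the engine; the object-level
selector breaks ties uniformly at random — after the first mutation
generation, exact ties have measure zero.  All randomness flows through
one `numpy` Generator per run; ensemble members draw their streams from
`SeedSequence(master_seed).spawn(n)`, so every logged number is
reproducible bit for bit from `(config, seed)`.

## Choosing the ecological constants

The vital-rate and food constants are not free stylistic choices; most
combinations produce an ecology that cannot support the phenomena at all.
Three quantitative constraints fixed the defaults (all diagnosed on
mechanistic observables — persistence, population size, per-lifetime
success counts):

1. **Viability.**  Under the linear age hazard the mean lifespan is
   `~sqrt(pi * c_d / 2)`.  With range-1 perception, finding food takes
   tens of steps, so lifespans must span several search cycles:
   `c_d = 25,000` gives a mean lifespan of ~200 steps.  Founder policies
   are random, so the founding population must survive several generations
   of policy selection on its energy subsidy; a high food cover of
   single-unit items (75% of cells, `phi_max = 1`) makes minimally
   competent policies ("eat when standing on food") viable and makes the
   bootstrap robust across seeds for reactive agents too.
2. **Bounded population.**  Without density-dependent death, the
   population grows until mean energy pins at `c_r / lifespan` and
   per-capita intake at about `c_r / lifespan^2`; total food throughput
   `|F| * mean quantity` then sets the population ceiling.  The defaults
   put the food-limited equilibrium near 6,000 agents at the reduced
   scale.
3. **The fast-learning regime.**  The veering analysis concerns learning
   that is as fast as the environmental change: the plastic skill must
   traverse most of `[0, 1]` within a small fraction of a lifetime.  The
   equilibrium allows ~7-9 successful forages per lifetime (see 2.), so
   `delta_s = 0.25` lets a newborn generalist reach a season's specialist
   skill within its first few successes and forage near the specialist
   rate thereafter.

`c_r = 1800` balances constraints 1 and 2.  Reproduction uses the current
(split-able) energy store rather than literal cumulative intake, making
the energy split at birth meaningful; a config flag restores the literal
cumulative-fitness reading.

## Experimental protocols

All protocols run 20-member ensembles with per-arm *paired* seeds (run
`i` of every arm shares a seed) at the reduced scale: 20x20 grid, 300 food
cells, 60 founders at aptitude 0.5, `L = 20,000` steps.  Assimilation runs simulate
one to two long seasons (the assimilation comparison is computed over the
first season only, so longer runs change nothing about the ordering).

* **Assimilation (Baldwin effect).**  Three agent-type arms under the
  long season (3,000 steps, the slowly-changing regime).  Genetic
  assimilation is the population mean of `|alpha - target(season)|`, the
  target being the season-favored specialist; the per-run summary is its
  mean over the first season, and arms are compared per seed pair.
  Action learning speeds assimilation (better foraging raises the
  population's reproductive throughput and hence the selection response);
  skill learning slows it (the plastic skill shields the genotype from
  selection).
* **Veering.**  Reactive and action+skill-learning arms under the short
  season (200 steps, about one lifespan, many generations per cycle
  faster than genetic tracking).  The final-epoch aptitude histogram (mean
  over the last `L/20` steps, 20 bins) is summarized by its modal bin, the
  mass in the outer 10% of either end, and the mass in `[0.35, 0.65]`.
  Runs that go extinct are excluded from the ensemble mean and counted.
* **Behavior evaluation.**  Reactive, non-reproducing populations forage
  for 2,000 steps in a static half-and-half environment: two populations
  carry genomes sampled (with replacement) from the veering arms' final
  populations, and two scripted baselines carry a hand-crafted competent
  forager policy with prescribed aptitudes (all 0.5; or 0.05/0.95
  halves).  Giving the baselines a fixed competent policy makes their
  behavior attributable to aptitude alone.  Populations are compared by
  the lifetime diet-ratio histogram, pairwise L2 norms, and Shannon
  diversity of resource use pooled over the population (ARD) and averaged
  within individuals (WID).

## The analytical model

A reactive individual with skill `s` has fitness
`W = pi0 * s^q + (1 - pi0) * (1 - s)^q`.  A plastic individual can express
any skill within `delta` of its aptitude and adopts the best reachable
skill per resource at linear cost `c * delta`:

    W(alpha, delta) = pi0 * min(1, alpha + delta)^q
                    + (1 - pi0) * min(1, 1 - alpha + delta)^q  -  c * delta

Scanned on a 0.01 lattice with `q = 2`, `c = 0.1`, `pi0 = 0.5`: at
`delta = 0` the optima are the specialists {0, 1}; for `0 < delta < 0.5`
the per-delta optima are the symmetric pair `{delta, 1 - delta}` moving
inward; at `delta = 0.5` they merge into the unique generalist
`alpha = 0.5`, which is also the global optimum — a genotype that is never
expressed as the plastic response (the veering attractor).  For `c = 0`
fitness is non-decreasing in `delta` and every `delta >= 0.5` is globally
optimal at the center; for `q = 1, c = 0` the center is optimal exactly
at `delta = 0.5`; for `q < 1` interior aptitudes win at every `delta`
(no specialist-to-generalist transition; the threshold finder reports
none).  Optima are reported as tie *sets* (tolerance 1e-9), never broken
silently; the threshold is the smallest scanned `delta` whose optimal set
contains 0.5 and no extreme.

## What the synthetic world does and does not show

The generator emulates the qualitative structure of a seasonal two-
resource foraging ecology: scramble competition through depletion,
energy-mediated reproduction, age-hazard mortality, and heritable
behavior.  It does not emulate metabolically realistic energetics,
spatially structured resources, perception noise, or more than two
resources, and the population sizes and timescales are chosen for desk
reproduction rather than matched to any organism.  Passing tests
demonstrate that the Baldwin speedup/slowdown and the veering attractor
emerge robustly in *this* model class under the stated regime (fast
learning, seasonal inversion, convex specialization trade-off); they are
not evidence about magnitudes in natural systems.

## Numerical notes and limitations

* Engine network math is float32; divergence from the float64 reference
  is well below behavioral relevance but makes trajectories sensitive to
  op ordering — reproducibility is guaranteed per build, not across
  refactors.
* `skill` is clamped to `[0, 1]`; at `q > 1` the extremes are nearly
  absorbing for skill learning (success on the opposite type becomes
  vanishingly rare), which is the mechanism making wrong-season
  specialists costly.
* Histograms bin `[0, 1]` into K equal bins with the right edge closed at
  1; the veering summaries use K = 20.
* Populations can go extinct (logged, never an error); protocol summaries
  exclude extinct runs and report their count.
* The analytical scan is exhaustive on the lattice; no continuous
  optimization is attempted, so optima are reported at lattice resolution.
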