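# Methods

## Model overview and assumptions

`foragesim` is a spatially explicit individual-based model of herbivore
foraging under scramble and contest competition.  Its purpose is to ask
how *gregariousness* — an individual's tendency to keep conspecifics
nearby — interacts with resource characteristics (abundance, spatial
clumping, patch quality, extraction speed, renewal frequency) to shape
foraging outcomes: energy intake, travel distance, and the month-to-month
variance of intake.

Key simplifying assumptions, deliberate and load-bearing:

- Agents have **no memory** of resource locations and no goal-directed
  travel; they sense only within fixed detection radii.
- Movement costs **no energy**; foraging costs are expressed as time and
  distance, not as an energy budget.
- Agents do not follow optimal-foraging patch-leaving rules: they extract
  a constant amount per tick until the patch is empty, then leave.
- No reproduction, mortality, predation, sexes or ages; the population is
  fixed for the length of a run.
- One food type per world; regrowth is **global** (the whole landscape at
  once), resembling a seasonal flush rather than per-patch recovery.

## Space, time, and entities

The world is a square torus (both axes wrap) of `side × side` patches,
default 281 (78,961 patches).  A patch is 10 m × 10 m, so the default
world is ~7.9 km².  Agent positions are continuous; the patch containing
an agent is the floor of each coordinate.  Headings are degrees clockwise
from north.  A tick represents ~30 minutes of daylight, 24 ticks a day;
the default run is 4,300 ticks (~6 months).

Patch state: `quality` (maximum energy, fixed integer), `penergy`
(current energy, 0 ≤ penergy ≤ quality), `extraction_rate` (energy one
agent removes per tick, fixed float).  Agent state: position, heading,
`stored_energy` (starts at 30, non-decreasing), `rhp` (fixed integer
competitive strength, uniform on 1–8), `xp` (learned fighting
self-estimate in [0, 1], starts 0.5), the last five fight outcomes, and
activity/distance/intake counters.

## Parameters

| parameter | units | range | default (midpoint) |
|---|---|---|---|
| tgt_neighbor | conspecifics | 0–11 (integer) | 6 |
| tgt_distance | patch-lengths | 1–49 | 25 |
| abundance | energy units | 200,000–1,200,000 | 700,000 |
| energy_per_capita | energy units | 4,000–9,000 | 6,500 |
| clump_size | patches | 0–500 (integer) | 250 |
| qual_mean | energy units | 25–150 (integer) | 88 |
| qual_sd | energy units | 1–20 (integer) | 10 |
| regrowth_rate | fraction of quality | 0.5–1.0 | 0.75 |
| patch_regrowth_interval | ticks | 500–3,000 (integer) | 1,750 |
| extraction_rate_mean | energy/tick | 2–8 | 5 |
| extraction_rate_sd | energy/tick | 0–3 | 1.5 |
| movement_noise | degrees | 10–45 | 27.5 |
| max_move | patch-lengths/tick | 25–50 | 37.5 |
| resource_detection_radius | patch-lengths | 50–100 | 75 |
| other_primate_detection_radius | patch-lengths | 50–100 | 75 |

`population = floor(abundance / energy_per_capita)` (22–300 over the
ranges above).  The default configuration — every slider at its midpoint
— is the calibrated *general scenario*.

**The extraction-rate upper bound.**  The bound of 8 is pinned by the
calibration bands rather than taken from a table.  The energy available
in a run is essentially closed: the initial abundance plus the capped
global regrowths (≈ 2.5 × abundance at the midpoint regrowth settings).
Since an agent either eats or moves every tick, the moving:eating ratio
is `(1 − f)/f` with `f ≈ available_energy / (extraction_rate × ticks ×
population)`.  Requiring the midpoint configuration to sit inside the
primate activity-budget band (0.25–0.6) forces the midpoint extraction
rate into roughly 5–6 energy/tick, i.e. an upper bound near 8.  Measured:
a midpoint rate of 5 yields ratios of 0.29–0.33 and daily paths of
1.5–1.7 km across seeds (both bands comfortably satisfied); a midpoint
rate of 8 yields ratios of 1.07–1.12, structurally outside the band.
Parameter sweeps that explore faster extraction (the scenario analyses
plot rates well above this slider range) remain possible by overriding
the range check in fixtures or scenario registries.

## Landscape generation

Clumps are created until the cumulative allocated energy reaches
`abundance`:

1. a uniformly random center patch;
2. a clump patch count drawn from Normal(clump_size, max(1, 0.1 ·
   clump_size)), rounded, floored at 1 (the clump-count spread is not
   dictated by anything observable, so it is set proportional to the
   mean);
3. members are the nearest not-yet-filled patches to the center in torus
   distance.  The fill order is a canonical offset order precomputed once
   (sorted by wrapped distance, then offset dy, then dx) — deterministic
   under a fixed seed and O(1) per clump rather than a per-center sort of
   the whole grid;
4. each member receives an integer quality ~ Normal(qual_mean, qual_sd)
   truncated below at 1, `penergy = quality`, and an extraction rate ~
   Normal(extraction_rate_mean, extraction_rate_sd) truncated below at
   0.1 (avoids zero/negative-rate pathologies).

Allocation stops at the patch that carries the total past `abundance`
(overshoot < one patch's quality).  Clumps may overlap; energy a
saturated region cannot hold is carried into a fresh clump with a fresh
size draw.  A grid that fills before reaching `abundance` raises an
explicit saturation error naming the unplaced energy.

Agents spawn at the centers of 5 resource patches chosen uniformly
without replacement (so early search does not inflate the variance
statistics), with uniform headings and uniform RHP.

## Scheduling

Per tick, in order: (1) agents act once each in a freshly shuffled random
order — an agent on an energized patch may start a fight and then eats
(unless it was the evicted loser); an agent on an empty patch senses and
moves; (2) after all agents acted, every agent's xp decays one step;
(3) on ticks that are positive multiples of the regrowth interval, the
landscape regrows (after agent actions).  Sensing always uses current
positions, so agents earlier in the order may already have moved — the
sequential-execution semantics of the original formulation.  A single
global RNG stream consumed in this fixed order makes runs bit-reproducible
under a seed.

An agent evicted before its turn forfeits the whole turn; evicted after
eating, it only flees.  The flee destination is a uniformly random Moore
neighbor of the contested patch — the minimal displacement consistent
with being chased off.  Only the turn-taking agent can initiate a fight,
one opportunity per turn, opponent drawn uniformly from co-occupants.

## Fights and xp

Benefit compares the gain in expected share of the contested patch
against the mean energy of the 8 Moore neighbors; when that mean is 0 the
benefit is set to 1 (all local energy is in the contested patch — the
maximal-benefit case).  Both B and C live on [0, 1] and are weighed
equally: `P(attack) = B/(B+C)`, 0 when B = 0.  The higher RHP always
wins; the aggressor loses ties.  Winners gain 0.01 xp unless already
above 0.98; losers lose 0.01 unless already below 0.02; each tick xp
relaxes toward the mean of the last five outcomes (0.5 before any fight)
by at most `XP_DECAY = 0.001` without overshoot.  The decay step is an
exposed constant: it only needs to be small relative to the ±0.01 fight
step so that fights, not relaxation, dominate within-day dynamics.

## Movement

Dispatch, for an agent on an empty patch:

- no visible resources and (no visible conspecifics or tgt_neighbor = 0)
  → **wander**: heading += uniform(0, movement_noise) − movement_noise/2;
- no visible resources, visible conspecifics, tgt_neighbor ≥ 1 →
  **travel**: heading toward the sensed conspecifics (the nearest,
  capped at tgt_neighbor, per the sensed-set definition), plus the same
  noise term (noise applies to wandering and traveling alike);
- visible resources and gregariousness satisfied (≥ tgt_neighbor others
  within the closed ball of tgt_distance; trivially satisfied at 0) →
  **forage**: keep the current goal patch while it remains visible and
  energized, else pick the visible patch with maximum energy (ties:
  nearest, then lowest row-major index); head toward its center;
- visible resources, rules not satisfied → **cohere**: head toward the
  wrapped centroid of the sensed conspecifics beyond tgt_distance; if
  none are beyond it, revert to foraging for this tick.

The step is `min(max_move, distance-to-goal)` when a goal patch exists
(landing exactly on its center and clearing the goal), else a full
`max_move`.  Directions toward multiple agents average the minimal-wrap
displacement vectors — well-defined on a torus.  Distance ties in the
nearest-conspecific sort break by ascending agent id.

## Output metrics

- **energy intake rate**: mean over agents of (total intake / ticks);
- **daily distance**: mean over agents of distance/(ticks/24), in
  patch-lengths/day and ×10 in m/day;
- **windowed intake variance**: per agent, intake summed over complete
  non-overlapping windows (720 ticks ≈ monthly, analyzed; 360 ticks
  recorded), sample variance (n−1) across windows, trailing partial
  window discarded; population mean of the per-agent variances (the
  per-agent-then-average reading matches how the other metrics are
  averaged across the population);
- **moving:eating**: per-agent `ticks_moving / ticks_eating`, averaged
  over agents that ate at least once (never-eaters are excluded with a
  warning count);
- **pattern flags**: daily path in [0.25, 4.0] km and ratio in
  [0.25, 0.6], closed intervals.

## Sensitivity screening

Morris one-at-a-time trajectories on the unit hypercube: p = 8 levels,
Δ = p/(2(p−1)) = 4/7, base points on the grid {0, …, 1−Δ}, each
trajectory perturbing every parameter exactly once in random order with
random feasible direction.  Elementary effects are signed differences
divided by Δ; with Δ in rescaled units, μ* (mean |EE|) and σ (sd of EE)
carry the units of the output, read as "effect of sweeping the full
range".  r is configurable; the desk default is r = 4 (44 runs for the
10 screened parameters).  Full-scale screenings on the order of
800 runs are reproduced by raising r (r = 72 gives 792).  Integer
parameters are rounded at evaluation time only; degenerate ranges are
excluded with a warning.

Ten parameters are screened in hypothesis scenarios; the five
pattern-matching-only parameters (qual_sd, regrowth_rate, movement_noise,
both detection radii) are held at mid-range.  The scenario registry
restricts extraction_rate_mean and patch_regrowth_interval to the upper
thirds of their ranges (*fast_slow*: fast-extracting, slow-renewing —
high depletability) or the lower thirds (*slow_fast*), other ranges
unchanged.  Thirds are a registry convention, adjustable per scenario.

## Problem sizes for testing and screening

The calibration checks and the acceptance script run the **full-scale**
world: 281-side, 4,300 ticks, five seeds (~25 s/run here).  Trend and
screening checks use two desk scales chosen to preserve density (abundance
scaled by the area ratio so energy/patch and agents/area are unchanged):

- **101-side, 1,500 ticks** for travel-distance effects, which are large
  and appear quickly;
- **141-side, 4,300 ticks** for intake-variance effects and Morris
  screening.  Variance needs five complete monthly windows and a
  non-trivial population: with only two windows the statistic is
  dominated by the initial depletion transient and the
  comfort-zone-vs-variance effect actually reverses.  The regrowth
  interval spans 500–3,000 ticks, so shortened runs would silence most of
  that parameter's range; desk-scale screening therefore keeps the full
  run length and shrinks the world instead.

A caveat that the desk scales expose: max_move (25–50) and tgt_distance
(1–49) are fixed in *patch-lengths*, so shrinking the world inflates
their leverage relative to landscape-driven parameters.  In the r = 4
desk-scale screening of daily distance, extraction_rate_mean's μ* is
statistically tied with max_move's (the EE dispersion at r = 4 is of the
same order as the μ* differences) and can rank below it; at full scale
the depletability parameters dominate.  Rankings from r = 4 screenings
should be read with that sampling error in mind — r = 4 is a smoke-test
resolution, not an inference-grade design.

## What the generated worlds do and do not emulate

The clump generator reproduces the spatial statistics the model is
sensitive to — clumped-to-uniform gradients, quality heterogeneity,
per-patch extraction heterogeneity — under exact energy-budget control.
It does not emulate real vegetation maps: no spatial autocorrelation in
quality beyond clump membership, no anisotropy, no seasonality within a
run (one global regrowth clock), and agent densities are tied to
abundance by construction.  Passing tests therefore demonstrate the
internal logic of competition and gregariousness on controlled
landscapes, not predictions for any particular habitat or species.

## Numerical choices

- Distances are Euclidean with minimal per-axis wrap; agent-patch
  distances are center-to-center.
- The Moore (8-cell) neighborhood defines both the fight-benefit
  denominator and clump/flee adjacency.
- Quality draws are rounded then floored at 1; extraction floored at 0.1.
- penergy is stored as float (extraction rates are fractional);
  regrowth caps at quality exactly.
- Sample variance uses n−1; windows are aligned to tick 0.
- Co-occupant eating is sequential in turn order; the second agent takes
  the remainder of a nearly empty patch, so patch decrease always equals
  summed gains.
- Seeds: a run consumes one `numpy` PCG64 stream seeded from the config;
  batch drivers spawn child seeds via `SeedSequence` (< 2³¹).

## Known limitations

- No predation, memory, diet mixing, energy-based movement costs, or
  demography (by design, see assumptions) — conclusions about the
  *benefits* of gregariousness are limited to intake-variance buffering.
- Global regrowth makes renewal landscape-synchronous; per-patch regrowth
  clocks would likely weaken the month-scale variance effects.
- The moving:eating ratio is nearly determined by the run's energy budget
  (see the extraction-bound note), so it is diagnostic of depletability
  settings rather than an independent behavioral outcome.
- Fight-decision sensing is local (the contested patch and its 8
  neighbors); agents never avoid stronger competitors proactively.
- r = 4 Morris screenings have large μ* sampling error; use them for
  coarse triage and raise r for publication-grade rankings.
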