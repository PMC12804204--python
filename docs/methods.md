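# Methods

## Model

Agents are characterised by sex (male/female), age band (15-29, 30-59,
60-75) and education (low/middle/high) — 18 categories — plus three grid
cells (one per 8-hour slice: night, day, evening), a continuous opinion
`o ∈ [0,1]` (conviction that eating five portions of fruit and vegetables a
day matters), a binary behaviour (healthy = currently meeting the 5-a-day
target) and two fixed constraint flags (household habits, budget).

One step is one slice. Steps cycle night → day → evening, starting at night
(agents begin at their residence). Each step is synchronous: exposure,
reward and the switch draw all read the state as of the start of the step,
so results are independent of agent iteration order. The update chain is
reward → exposure → opinion → behaviour, as described in the README. The
reward cap `min(1, (1+HDR)·o)` is applied before the inertia mix. A run is
18 steps (6 simulated "days"), each day standing for one of the six years
between the 2002 and 2008 survey waves; results beyond that horizon are not
meaningful and the code does not encourage them (`n_days` is a parameter,
but the calibrated defaults assume 6).

### Singleton cells

Exposure is the healthy share among the *other* occupants of the agent's
cell. An agent alone in its cell has no exposure; by convention the
`(1−IC)` term is dropped entirely and the (rewarded) opinion keeps full
weight. The alternative — treating missing exposure as 0 — would
systematically erode the opinions of isolated agents, which has no
behavioural justification.

### Free parameters

| parameter            | range    | default | role |
|----------------------|----------|---------|------|
| healthyDietReward    | [0, 1]   | 0.153   | multiplicative opinion reinforcement for agents who behaved healthily; 0 = no reward |
| opinionInertia       | [0, 1]   | 0.820   | weight of own (rewarded) opinion vs cell exposure; 1 = opinions never respond to others |
| maxProbaToSwitch     | [0, 1]   | 0.890   | ceiling of the opinion→switch mapping; 0 = frozen behaviour |
| constraintStrength   | [0, MPS] | 0.129   | per-constraint shift of the ceiling |

The defaults are the calibrated values shipped with the package (the
intermediate-reward member of five maximally diverse acceptable sets from
the calibration workflow). The tighter coupled
box `MPS ≤ 1 − n·CS`, `CS ≤ MPS/n` is mutually inconsistent with those very
values at `n = 2`, so the implementation enforces only `CS ≤ MPS`, clamps
every final switch probability to [0, 1], and emits a warning when a
parameter set falls outside the advisory box.

## Initialisation

Behaviour ~ Bernoulli(category's 2002 healthy share); opinion drawn
conditionally on (category, behaviour); constraints ~ independent Bernoullis
of the category prevalences (the surveys give only marginals; independence
is the minimal assumption). The per-category survey quantities are shipped
as a versioned fixture (`src/fiveaday/data/group_profiles.csv`, 18 rows,
validated for completeness at load).

Opinion distributions: when empirical quintile bins are supplied (an
optional fixture: bin edges + masses per category × behaviour), a bin is
drawn by mass and the opinion uniformly within it. Otherwise a normal with
location = the category's observed mean opinion and sd 0.15, truncated to
[0, 1], is used. The sd is a declared default, not an empirical value; the
truncation shifts the realised mean by up to ≈ 0.03 at location 0.8, which
the tests account for by asserting against the theoretical truncated-normal
mean rather than the raw survey mean.

## Synthetic population (around-the-clock allocation)

Night cells: agents are created from zone × category counts; each draws a
night cell from its zone's cell-weight table. At toy scale zones coincide
with cells (weight 1); real census-block geometries would enter only through
that weight table, so no GIS machinery is needed.

Day/evening cells, three steps: (1) per (category, night cell, slice), the
probability of each destination cell is the share of cumulative
respondent-minutes that survey respondents with that profile and night cell
spent there during the slice (stays are pre-split at slice boundaries by the
reader, so the arithmetic is exact in integer minutes; respondent survey
weights are not modelled — minutes are unweighted); (2) missing entries are
filled from the nearest (Euclidean centroid distance, ties to the smaller
cell id) night cell with an observed entry of the same category and slice —
day and evening donors are searched independently; (3) agents draw their
cells from these laws, falling back to the opposite-sex entry (same age,
education, night cell) and finally to immobility (day = evening = night), so
the assignment is total. Provenance (observed / interpolated / opposite-sex
/ immobile) is recorded per agent and per table entry.

Scenario randomisation replaces the targeted slice cells of a Bernoulli(p)
subset of agents with uniform draws over populated cells; night
randomisation never touches categories, so category totals are conserved by
construction.

## Toy regions

The generator emulates three features of large-city inputs: (i) residential
education segregation — each education level's residential law is the
mixture `(1−s)·uniform + s·band`, with low/middle/high bands occupying the
left/centre/right thirds of the grid, so `s = 0` is unsegregated and `s = 1`
near-disjoint (any monotone-in-s family with those limits would do; the
mixture makes the limits exact); (ii) daily mobility toward a few hub cells
with exponential distance decay; (iii) category-dependent mobility
propensities (more mobile: higher educated, men, the middle age band —
matching the qualitative survey gradients). Defaults: 15×15 grid, 10⁴
agents, s = 0.8, 4 hubs, decay 0.35, one synthetic survey respondent per
(category, inhabited cell).

What the toy region does *not* emulate: real geography and density
gradients, household structure, the 100 m pre-gridding of real trip data,
weekday/weekend contrasts, or correlation between education and age/sex in
space. Passing tests therefore demonstrate the mechanisms (segregation
amplifies the education gradient, mixing erodes it), not city-scale
magnitudes.

## Metrics

* **EII**: population-weighted sum over the six sex × age strata of the
  high/low-education healthy-share ratio; the middle group is ignored by
  construction. A zero healthy count in a stratum's low or high group
  triggers a continuity correction (+0.5 healthy in both groups) with a
  warning; a stratum with an empty education group is skipped and the
  weights renormalised, with a warning. Neither correction is silent.
* **Duncan** is computed group-vs-complement per slice.
* **Moran's I** uses row-standardised queen contiguity by default (rook and
  distance-band available); the statistic is implemented directly (the
  neighbourhood structure of a regular grid makes a dependency on a spatial
  weights library unnecessary) and is cross-checked in the tests against a
  brute-force evaluation of the definition.
* **Erreygers** corrected concentration index `E = 4µC` with fractional
  education ranks (ties = average rank); rank-ordered and age/sex-blind,
  complementing the stratified EII.
* Calibration distances: `Δ_Health` = Σ over the 18 groups of
  |simulated − target healthy counts|; `Δ_EII` = |EII gap|.

## Calibration

NSGA-II (real-coded, SBX η=15, polynomial mutation η=20, binary tournament
on rank/crowding) is implemented in `fiveaday.optim` and validated against a
toy bi-objective with a closed-form Pareto front. The genotype is
(HDR, IC, MPS, CS/MPS) on the unit box so the coupled constraint CS ≤ MPS
holds everywhere. Objectives are averaged over a configurable number of
seeded replicate runs per candidate (default 3) with common random numbers
across candidates; how the original experiments handled objective noise is
not documented, and averaging is the conservative choice.

The diverse acceptable-set search (`acceptable_sets`) is a deliberately
simplified stand-in for OSE (origin-space exploration with adaptive
rejection zones): Latin-hypercube sampling, threshold rejection, local
refinement of near-misses, then greedy max-min selection in the normalised
box. It is labelled non-equivalent to OSE in its result object and
docstrings and is validated only for recovery behaviour at toy scale.

## Numerical choices and problem sizes

* All randomness flows from `numpy.random.Generator`; replicate *r* of a
  battery uses seed `base_seed + r`. The vectorised engine and the plain
  per-agent reference loop consume one uniform per agent per step in
  agent-index order, making their trajectories bit-identical under a shared
  seed (this equivalence is asserted in the tests).
* Presence-table distributions must sum to 1 within 1e-9; nearest-neighbour
  ties break on the smaller cell id; groups in the slice assignment are
  processed in (category, night cell) lexicographic order for determinism.
* Scenario experiments in the test suite use the declared toy defaults
  (15×15, 10⁴ agents) with 200 replications per scenario for the directional
  comparisons, 60 per point for the mixing sweep, and a reduced toy
  (10×10, 3000 agents; NSGA-II 12 × 8 generations × 2 runs/evaluation) for
  the self-calibration recovery check. These sizes give medians whose
  Monte-Carlo error is well below the effects being tested while keeping the
  default run a few minutes long.

## Known limitations

Agents' attributes, residences and mobility laws are fixed for the whole
run (no ageing, migration or behavioural feedback on mobility); households,
income, food environment and opinion models richer than inertia+exposure
(e.g. bounded confidence) are out of scope. The EII is undefined without
both education extremes in a stratum — small populations rely on the
logged corrections, so very small runs should prefer the Erreygers index.
City-scale empirical magnitudes (million-agent populations built from real
census, mobility and nutrition surveys) are not reproducible from the
bundled synthetic inputs; the package reproduces the directional findings
at toy scale.
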