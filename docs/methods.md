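# Methods

This note documents the models implemented in `tmesim`, the defaults and the
reasoning behind the choices that were genuinely open.

## Lineage data model

A lineage database is a flat table of cell generations. Each record lives
from `birth_time` to `fate_time` (minutes) and ends in BD, MD, CD, CF or
ALIVE_END. Structural invariants are enforced on read and on demand: parent
references resolve, a BD cell has exactly two children and an MD cell exactly
`md_poles ≥ 3`, CD/ALIVE_END cells have none, fusion partners share one fate
instant and their product records both parents, every child's birth equals
its parent's fate time, and progenitors are born at time 0. Acyclicity
follows from the strict time ordering. `fate_time == birth_time` is legal
only for an ALIVE_END record at the observation end (a cell born in the final
frame). Empirical data is frame-based (10-min default); simulated data
carries real-valued times. The CSV/JSON schema is original to this package
(versioned header; semicolon-joined parent ids in CSV so fusion fits a flat
row); serialization uses shortest-exact float representation so round-trips
are byte-stable.

## Lineage analytics

The population curve counts records with `birth ≤ t < fate`, ALIVE_END cells
counted through the observation end; optional normalization rescales the
series to a chosen count at the first time point. Fate patterns ("CF > BD"
etc.) are counted **per product cell** — a fusion product has two CF parents
but increments its pattern once. Doubling times are durations of BD-fated
cells born of a BD. Per-lineage SNA1 totals sum every present value
(back-propagated internal generations included) and are binned at
2000/4000 units, boundaries assigned upward (2000 → mid, 4000 → high), with
an ordinary-least-squares regression of total SNA1 on lineage size.
"Reproductive" MD-progeny means: the cell is an MD product or descends from
one and itself divides bipolarly; the fraction divides by the count of cells
alive at the observation end. Products still alive at the observation end
enter no pattern numerator (their next fate is unknown); that convention is
fixed here and tested.

## Expression back-propagation

Only cells alive at the end of imaging are stained, so ancestral α2-6Sia is
reconstructed bottom-up: each cell with descendants receives the arithmetic
mean of its children's post-propagation values. Dead branches (CD leaves)
carry no measurement and are excluded from the average rather than treated
as zeros — death is not evidence of non-expression. A fusion product's value
propagates to both parents equally (symmetric; no information favors either
partner). Lineages with no measurement anywhere are left untouched with a
warning. The operation is idempotent. The expression list holds one entry
per valued cell across **all** generations, zeros included, with the
observed maximum `v_max` kept as the resistance reference.

## Event-transition model and fate simulation

The model stores, per prior event (progenitor start, BD, MD, CF), the raw
multiset of observed `(next event, duration)` pairs plus the censored
durations of cells still alive at the observation end. Transition
probabilities are empirical frequencies over completed events only;
simulation resamples the observed pairs jointly, preserving the joint
structure of event type and waiting time with no parametric assumptions.
Censoring is never sampled: it re-emerges when a sampled event falls beyond
the simulation horizon.

Progenitors start at a uniform random phase of their first sampled wait, so
a deduced population begins desynchronized across the cell cycle. BD spawns
two daughters; MD an arity resampled from the observed pole counts; CD
nothing.

**Fusion bookkeeping.** Every fusion leaves *two* CF-fated records in a
database — the initiator and the recruited partner, whose own next event was
pre-empted. Two consequences are built in:

* a cell that samples CF initiates a fusion only when its sampled duration
  lies in the upper half of the fitted CF durations for its prior (the
  truncated partner lifetimes populate the shorter half); otherwise the
  event is redrawn among the non-CF alternatives. This halves initiations
  and restores initiator-like fusion clocks;
* the partner is recruited among concurrently alive cells of the lineage,
  weighted by each candidate prior's own CF share, so each prior's realized
  CF rate matches its fitted rate in expectation.

Without these corrections, a fit→simulate→refit loop measurably inflates the
fusion rate (≈2× from double-initiation; a further ≈25% from resampling
truncated partner clocks). With them the loop recovers all transition
probabilities within sampling error, which the acceptance suite verifies at
3 binomial standard errors on ≥2000 events.

**Expression assignment.** At each bipolar division the daughters receive
α2-6Sia values only when at least one expressing source cell (sna1 > 0 after
back-propagation) has a BD→BD doubling time within ±10% of either daughter's
sampled interval — the expressing subpopulation divides on a narrow clock,
so deduced cells inherit expression only when their tempo matches. The first
daughter draws uniformly from the expression list (zeros included), the
second uniformly within ±15% of the first. The population-average variant of
the gate is available via `gate_mode="average"`. Non-BD daughters and failed
gates keep expression absent. Scaling multiplies assigned values by an
arbitrary positive factor (1.5/1.0/0.5/0.25 model the in-vivo variation
range), capped elementwise at `v_max`.

## TME landscape categorization

Composition tables are percentages per cell type per cancer case. Category
fractions are plain sums over member types divided by 100; they are
independent cancer:category ratios and are deliberately not normalized (they
may sum above 1). M1 macrophages and neutrophils are recognized but excluded
(context-dependent dual roles). Column labels vary across exports, so
resolution goes through an editable alias map; unknown columns are reported,
never silently dropped. Agent counts are `round(n_cancer × fraction)`
(banker's rounding; the documented examples — 225 at 45% of 500, 250 at
ratio 1:0.5 — are exact under any convention).

## 3D TME simulation

Cancer progenitors and microenvironment agents are placed i.i.d. uniform in
a solid sphere (radius 50 px; direction × radius·U^(1/3), verified against
the (r/R)³ radial CDF). Daughters are rejection-sampled uniformly within
6 px of the parent anchor until inside the sphere (100 tries, then radial
projection). Display motility (≤2 px) never enters effect geometry: anchors
are static, so a cell's nearest-agent set is constant over its lifetime.

Because geometry is static, suppressive/permissive effects apply at most
once per cell, and a lethal agent triggers only on first encounter, each
cell is resolved exactly once — at the first 10-min grid point of its life.
A per-timestep loop would re-evaluate an unchanged configuration; the
one-shot resolution is semantically identical and keeps 1331-point sweeps
tractable. Resolution casework: nearest lethal → resistance draw then
`s_lethal`% draw, on success the cell dies within that frame and its whole
subtree is removed; nearest suppressive (second not permissive) → resistance
draw, then the remaining wait and all descendant waits are multiplied by
`1 + s/100`; nearest permissive (second not suppressive) → no resistance
draw, waits multiplied by `1 − s/100` but floored at the population's
shortest BD duration (a wait already below the floor is left unchanged — the
floor limits shortening, it never extends); mixed nearest pairs use the
distance-weighted offset `max(0, s_near − s_far·d_near/d_far)`, which
reproduces the reference value 25 from strengths (50, 50) at distances
(3, 6) and decays smoothly. Daughters are born effect-eligible again but
inherit the accumulated duration scaling. Resistance maps normalized
expression linearly into `[1, r_max]`; the effect probability is its
reciprocal (5-fold maximum resistance → a 20% chance at full expression).
Permissive effects bypass the resistance draw: resistance is defined against
suppressive and lethal action only.

If duration rescaling desynchronizes a fusion pair, the fusion completes at
the later partner's arrival, both partners are recorded fusing at that
instant, and the product inherits the later partner's scale factor and
position; a partner orphaned by a lethal kill never fuses and survives to
the horizon. All randomness flows from one seeded generator in a
deterministic event order, so identical (inputs, seed) reproduce
byte-identical outputs; sweep grid points derive independent seeds from
(base seed, grid index) and are order-independent.

## Synthetic data generator

The generator is first-class, tested code and defines the study conditions
used throughout the tests. Defaults emulate a tracked cervical-cancer-line
population: log-normal division waits with median 1596 min (26.6 h) and
σ = 0.18; P(next | BD) = 0.90 BD / 0.03 MD / 0.05 CD / 0.02 CF; after MD or
CF the majority of progeny die (0.55 CD) and a minority re-divide —
aberrant events are rare and their products fragile. Tri-/tetrapolar MD
arities occur 9:1. Half the lineages are founded by α2-6Sia-expressing
cells (a mixed population, mirroring an expression list that is half zeros);
expressing lineages' waits concentrate within ±10% of the typical doubling
time at association strength 1. Terminal SNA1 values are log-normal (median
800, σ = 0.5 — a moderately dispersed per-cell fluorescence distribution
whose observed maximum sits a few-fold above the median, so a typical
expressing cell carries meaningful resistance relative to `v_max`). Fusion
uses the same initiate/recruit semantics as the simulator (fair-coin
initiation, CF-share-weighted recruitment) so realized rates match the
configured probabilities.

What the generator does **not** emulate: spatial correlation of tracked
cells, measurement noise in fluorescence, lineage-tracking errors,
cross-lineage fusion, and any coupling between expression and MD/CD beyond
the doubling-time association. Passing tests therefore demonstrate the
pipeline's internal consistency and its stated statistical properties under
these conditions, not fidelity to any particular cell line.

## Problem sizes and numerics

The test suite runs fixture populations of 40–100 lineages over 8000–10 200
min (thousands of cells), deduced populations of 100–500 progenitors, and
Monte-Carlo panels of 20–25 seeds at 200 progenitors over 6000 min — sizes
chosen so the full suite completes in well under a minute per property while
keeping ≥2000 events for recovery bounds and clear separation in the
monotonicity panels. Recovery checks use 3 binomial standard errors;
conditionals with fewer than 30 simulated events are not bounded (no
meaningful binomial band exists there). Placement goodness-of-fit uses a
Kolmogorov–Smirnov test at n = 10 000 against the closed-form radial CDF.
Ties in nearest-agent distance break by agent id; heap ordering makes event
processing fully deterministic.

## Known limitations

* Suppressive/permissive rescaling applies to *all* inter-event waits of the
  cell and its progeny (MD/CD/CF waits included), not only BD doubling
  times, for timeline coherence.
* The `apply_*` database-level operations rescale schedules without
  re-censoring at the observation end except for capping ALIVE_END records;
  the engine, not these helpers, owns horizon truncation during runs.
* A deduced ALIVE_END cell has no further schedule, so permissive or
  suppressive effects on it change nothing for itself (it has no
  descendants by construction).
* Killed subtrees do not free spatial slots; daughter placement ignores
  occupancy.
* Fusion partners are restricted to the same lineage; cross-lineage fusion
  would merge trees and is not represented in the data model.
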