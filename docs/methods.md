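# Methods

## The model

A signalling network is represented exactly like a metabolic network in
constraint-based analysis: *m* species (proteins, complexes, second
messengers) by *r* reactions in a stoichiometric matrix **S**, steady
state **S v = 0**, and bounds `l ≤ v ≤ u` on the flux vector.  "Flux"
here is the rate of a phosphorylation, binding or dimerisation event in
arbitrary units (AU); there are no kinetics and no objective function —
no biomass reaction exists in a signalling network, so all analyses are
polytope analyses (sampling, projection) rather than FBA optima.

All reactions are irreversible (`l ≥ 0`): a signalling step and its
reverse (e.g. a phosphatase acting against a kinase) are distinct
reactions when the pathway source distinguishes them.  Internal
reactions default to bounds `[0, 1000]` AU; 1000 plays the role of
"effectively unbounded" while keeping the polytope compact for
sampling.

### Modifiers, activators, inhibitors

Pathway databases annotate catalysing entities ("modifiers" — typically
phosphorylated upstream proteins) separately from the reaction's
substrates, leaving them stoichiometrically disconnected.  A modifier
`mod` of reaction `A → B` is rewritten as a co-substrate with a spent
form: `A + mod → B + mod_p`, plus boundary reactions `→ mod`
(production) and `mod_p →` (consumption).  The spent form avoids the
ambiguity of writing the same species on both sides, and the two
boundary reactions decouple the modifier's supply from the rest of the
network.  The spent species is suffixed `_p`, with a registry to avoid
collisions with existing ids.

Activators and inhibitors carry no stoichiometry at all; they enter
through the gene layer (below).

### GPR rules

Gene–protein–reaction rules are Boolean trees over gene ids: complexes
join their subunit genes with `AND`, isoform sets with `OR`, inhibitor
proteins are wrapped in `NOT`, and a reaction with both a modifier and
an inhibitor gets `modifier AND NOT inhibitor`.  Boundary reactions
created for a modifier inherit that modifier's rule; reactions with no
regulatory annotation carry no rule.

Evaluation is *ternary* over states `{+1 up-in-E, −1 up-in-M, 0
unchanged}` with `AND = min`, `OR = max`, `NOT = negation`.  The
ternary extension is the minimal monotone extension of the Boolean
intent that lets "unchanged" propagate neutrally; a strict two-valued
mode exists for callers with on/off data.  Consequences worth knowing:
a complex is only called when *every* subunit is called in the same
direction, and an isoform-set inhibitor only flips its reaction when
every isoform is called (the OR of the isoforms must reach −1 before
the NOT turns it into +1).

### Dead-end closure

A species only produced or only consumed blocks steady-state flux
through its reactions.  Closure opens a candidate exchange per species
(initially `[0, 0]`), forces every internal reaction to carry flux
≥ 1, and solves a MILP minimising the number of candidates whose
bounds must be relaxed, with big-M coupling (`M = 1000`) between the
relaxation amounts `p_j, n_j` and binary indicators `y_j`.  Selected
candidates become directed boundary reactions in the final model
(`→ X` when the upper bound was relaxed, `X →` when the lower);
unselected candidates are dropped and the forced lower bounds
restored.  For irreversible networks each dead-end species provably
needs its own exchange (no other column can balance a single-signed
row), which is why the embedded ground-truth oracle may enumerate over
dead-end species only and still be globally optimal.

Determinism: the MILP is solved in two stages — minimum cardinality,
then minimum total relaxation `Σ(p+n)` with a vanishing (1e-6-scale)
preference for earlier reaction ids.  The second-stage weights are far
below any meaningful relaxation amount (≥ 1 AU here) but make
equal-optimum solutions reproducible across solver versions.
Solver: HiGHS via `scipy.optimize.milp`, mip gap 0, integrality
tolerance 1e-6.

## Contextualisation

Expression tables carry signed relative fold changes (negative =
higher in the epithelial line) and p-values; genes with `|fold| ≥
cutoff` and `p ≤ 0.05` are called.  Cutoffs are dataset-specific
presets (D492: 2.0; MCF7/MCF10A: 0.5; HMLE: 0.3) on the table's own
scale, not log2 (a flag accepts log2 input).  Calls propagate through
GPRs to reactions; since upper bounds are effectively infinite,
up-regulation in one context is simulated by multiplying the
reaction's bounds by 0.01 in the *other* context model (1000 → 10).
Inhibition needs no special case: the `NOT` in the rule already
inverts the direction, so an inhibitor high in one context
down-regulates its target in that same context.  The tightening is
recorded in model metadata, making it idempotent — re-applying the
same calls to an already-tightened model is a no-op.

## Sampling

Artificially-centred hit-and-run (ACHR) over `{v : Sv = 0, l ≤ v ≤ u}`:
warm-up points are the optima of per-reaction min/max LPs (FVA), pulled
1% towards their centroid; directions are differences between a random
stored point and the running centre, projected onto the null space of
S; the step is uniform on the feasible segment.  Defaults: 5000
samples, thinning 100 (steps between stored samples), fixed seed —
fully deterministic given the seed.  The tests and the acceptance
script use thinning 10: at the problem sizes used there (r ≈ 30,
null-space dimension ≈ 10) chains decorrelate within a few steps, and
the diamond-network test verifies the sampled means against a
rejection-sampling oracle.  Every stored sample satisfies
`‖Sv‖∞ ≤ 1e-6` (drift is removed by re-projection each step) and the
bounds to 1e-9.

Comparison statistics: per-reaction fold `(v̄_M + ε)/(v̄_E + ε)` with
`ε = 1e-6` AU guarding zero-flux reactions; log2 folds (negative =
higher flux in the epithelial model); pathway aggregates as the
geometric mean of member folds (arithmetic by flag), exchange
reactions excluded from heat-map output by default.  Density estimates
(Gaussian kernel, Silverman bandwidth) are for reporting only; a
zero-variance marginal is reported as a degenerate spike, not an
error.  "Flux span" defaults to the mean flux — the convention of the
comparison it mirrors — with the max−min width available by flag.

## Reversal prediction

Given the mesenchymal model and the epithelial mean flux `v_E`, the
objective `min α‖v − v_E‖₂ + (1−α) Σ y_j` is a mixed-integer quadratic
program.  No MIQP solver being part of the stack, it is decomposed by
cardinality: for a fixed relaxed subset the inner problem is the
Euclidean projection of `v_E` onto the widened polytope (a convex QP,
solved in null-space coordinates with `trust-constr`), so the search
enumerates subsets in increasing size, pruning once `(1−α)k` alone
exceeds the incumbent — exact up to 12 candidates.  Beyond that a
violation-guided heuristic projects `v_E` onto the fully-relaxed
polytope, ranks candidates by how much the projection violates their
original bounds, evaluates prefixes of that ranking and prunes members
that do not pay for themselves; it agrees with the exact mode on all
test problems.  `alpha` defaults to 0.5 and is always reported; an
optional normalised variant divides the distance term by `‖v_E‖`
because the two objective terms have incommensurate units.  Relaxed
reactions map to genes via their GPR leaves; genes under a `NOT` are
flagged as inhibitors (the suggested intervention is suppression, not
overexpression).

## Crosstalk scoring

The sign table (+1: the pathway induces the metabolic gene; −1:
suppresses) composes with the pathway flux direction by sign
arithmetic: pathway higher in E (fold < 1) and sign +1 predicts the
gene down in the mesenchymal cells, and so on; a fold of exactly 1
makes no call.  Predictions are scored by exact matching against
observed directions; genes without detectable expression (`NA`) leave
the denominator.  Percentages are *truncated* toward zero at one
decimal (13/15 → 86.6), matching the convention of the curated
comparison table shipped in `src/emtflux/data/` (20 AKT-regulated
metabolic genes, 5 NA; 13/15 agree, GLUT1 and SREBF1 discordant).
The same gene directions constrain any GPR-bearing metabolic model
into a Met_E/Met_M pair with the identical 0.01 tightening mechanics,
compared by per-reaction span ratios with a ±5% "similar" band.

## Synthetic data

The generator emulates the pipeline's real inputs with known ground
truth: mass-balanced 1→1 irreversible networks on an acyclic topology
(chain / branch / diamond / random DAG — acyclicity guarantees dead
ends exist before closure), planted modifier/activator/inhibitor
annotations with 1–2 genes per protein, expression tables where
planted genes get `|fold| ≥ effect` (default 3, must exceed the
cutoff) at `p ≤ 0.01` and background genes stay below 0.8× the cutoff,
and random ±1 sign tables with analytically derived true directions.
Ground truth for the minimal-exchange stage is computed at generation
time by subset enumeration with an LP feasibility check per subset
(capped at 20 species / 14 dead ends to keep generation sub-second).
Identical specs produce byte-identical outputs.

What the generator does *not* emulate: correlated probe noise,
platform effects, many-to-many probe/gene mappings, reversible or
non-unit stoichiometry, and mass-action kinetics.  Passing tests
therefore demonstrate the correctness of the machinery (calls,
propagation, tightening, sampling, optimisation) under clean planted
signals, not robustness to real microarray noise.

A note on planted directions: planting *opposite* directions on
serially-coupled reactions can make the ground truth self-contradictory
— tightening the upstream reaction in one model caps the downstream
reaction there regardless of its own call.  The acceptance script
therefore plants co-directionally (all modifier genes up in E), the
analogue of one signalling arm being uniformly more active in one
phenotype.

## Known limitations

* The deposited pathway spreadsheets for the original EGFR study are
  not redistributed; the two tests that check their exact composition
  (182 reactions, 216 genes, 152 species, 83/99 split; the 5-reaction
  reversal set with 22 genes) require placing those files under
  `data/deposited/` and fail otherwise.
* SBML is import-only (species, reactions, modifiers); regulatory sign
  information and bounds are carried by the tabular/JSON dialects.
* The exact reversal search is exponential in the candidate count and
  switches to the heuristic beyond 12 candidates; the heuristic has no
  optimality guarantee.
* Percent truncation (not rounding) is a deliberate convention of the
  curated comparison table; use the reported exact fraction for
  further arithmetic.
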