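# Methods

## Reconciliation model

A biogeographic data-set couples one or more rooted, fully resolved taxon
cladograms with a mapping from each terminal to a non-empty set of areas
drawn from a fixed universe.  An area cladogram `H` — rooted, binary,
leaves exactly the universe — is scored against the data by embedding
every taxon-tree vertex `u` at a vertex `m(u)` of `H` and pricing each
taxon divergence:

* **vicariance** (cost `v`): the two daughters' associations lie in the
  subtrees of the two distinct children of `m(u)`;
* **sympatry/duplication** (cost `s`): both daughters remain within the
  subtree of `m(u)` without forming that vicariant split (both at `m(u)`,
  one at `m(u)`, or both inside the same child subtree);
* **dispersal/switch** (cost `d`): exactly one daughter jumps to a vertex
  outside the subtree of `m(u)`; the jump may target any non-descendant
  vertex — there is no timing constraint, matching parsimony-style tree
  fitting rather than time-consistent reconciliation;
* **extinction/sorting** (cost `e`): one unit per area-cladogram edge
  traversed downward between an event's prescribed starting vertex (the
  children of `m(u)` for vicariance; `m(u)` itself for staying lineages)
  and the daughter's realized association.  Jump landings are charged no
  extinctions — a jump-then-descend history is representable as a direct
  jump of the same dispersal cost.

Every embedding therefore has a unique event decomposition, and the total
cost is `v·n_vic + s·n_sym + e·n_ext + d·n_dis`.  A single-area terminal
must sit at its area's leaf.  Each clade's root attaches anywhere in `H`
at no cost; clade costs add.  Costs may be negative (the
maximum-codivergence regime sets `v = −1`): event counts are bounded by
tree size, so the optimisation cannot diverge.

Named regimes: `SC` = (0, 0, 1, 2) and `MC` = (−1, 0, 0, 0) for
(vicariance, sympatry, extinction, dispersal).

### Dynamic programme

`fit` computes, for every taxon vertex and every association, the optimal
value of the subtree below it.  Within a child's contribution three
auxiliary sweeps over `H` — best placement inside a subtree weighted by
`e` per edge (min-plus), best placement anywhere in a subtree, and best
placement outside a subtree — reduce each vertex's transition to O(1) per
association, giving O(n_taxa · n_areas) per fit.  The sympatry transition
is decomposed into disjoint cases (both daughters at `m(u)`; one at
`m(u)`; both strictly inside the same child subtree) so that no embedding
is priced under two different event types and none is counted twice.

Alongside the minimum cost the DP propagates, through the same
alternatives, the number of distinct optimal embeddings and elementwise
min/max event-count vectors over the optimal set (min-plus/max-plus
sweeps).  Ranges are exact without materialising embeddings;
`enumerate_optimal` backtracks through the tables (re-deriving each
transition by classifying all child-placement pairs) to list the optimal
embeddings in canonical order up to a cap.  Cost ties are compared at an
absolute tolerance of 1e-9; with integer regimes all costs are exact.

The test suite checks the DP — minimum cost, optimum count and event
ranges — against an independent brute-force enumerator over all
embeddings on hundreds of random small instances, and property-tests
monotonicity (raising one event's cost never lowers the optimum) and the
one-event-per-divergence accounting identity
`n_vic + n_sym + n_dis = n_terminals − n_clades` for single-area data.

### Widespread terminals

The cost semantics of a terminal assigned to several areas is not
determined by the model above, so it is a policy:

* `cheapest-single` (default): the terminal may sit at any one of its
  listed areas' leaves, optimizer's choice, no surcharge;
* `all-dispersal`: as above, plus one dispersal event per extra listed
  area (a widespread range read as recent dispersal);
* `all-free`: the terminal may also sit, free of charge, at any vertex on
  the paths from the most recent common ancestor of its listed areas down
  to them (a widespread range read as an undivided ancestral area).

The policy in force is recorded in every result object.

## Area-cladogram search

For `k` areas there are `(2k−3)!!` rooted binary leaf-labelled
topologies (3, 15, 105 for k = 3, 4, 5).  The search space is enumerated
exhaustively by leaf insertion, each topology exactly once, and every
candidate is fitted; 3 ≤ k ≤ 7 is enforced — beyond that an exhaustive
scan is impractical and no heuristic is implemented.  The optimal set is
reported in canonical (label-sorted) order, so results are independent of
the input order of areas.  Analyses need at least three areas for the
same reason phylogenetics needs three taxa.

## Permutation tests

* `pterm` shuffles the terminals' area-set blocks across the pooled
  terminals of all clades; the multiset of area sets is conserved.
* `ptree` replaces each clade's topology with a uniform draw over rooted
  binary topologies on its leaf set (equiprobable/PDA null, by sequential
  uniform grafting).  Permutation respects clade boundaries: terminals
  are pooled across clades for `pterm`, but topologies are redrawn within
  clades, so clade separation introduced by time-slicing is preserved
  under the null.

The cost test refits every replicate to each *fixed* tested cladogram (no
re-search), yielding one p-value per cladogram: the fraction of replicates
whose cost is less than or equal to the observed cost.  Conventions,
chosen conservatively and fixed:

* ties count toward the null tail;
* p-values are raw proportions, so p = 0 is reportable when the observed
  cost beats every replicate; an add-one corrected variant
  `(b+1)/(n+1)` is available behind a flag;
* with default settings, 10,000 replicates and alpha = 0.05.

When the tested cladogram is specified a priori the p-value is
exchangeability-exact: over null data its distribution is uniform, and
the measured type-I rate in the calibration experiment is ≈ 0.05.  When
the tested cladogram is the *search winner*, the observed cost is a
minimum over all candidates while each replicate is scored against the
selected hypothesis only, so per-tree p-values carry selection optimism
(measured ≈ 0.2 at alpha = 0.05 on null data with 15 candidates).  This
mirrors the one-p-per-optimal-tree reporting convention of event-based
tree fitting; hypothesis-level conclusions from searched optima should be
read accordingly, and `cost_significance(..., cladograms=[H])` is the
calibrated test of an a-priori hypothesis.

Event-frequency tests (by default `pterm` only) compare, per event type
and per tested cladogram, the observed optimal count with the replicate
distribution of optimal counts: `gtr` is the fraction of replicates with
at least the observed count, `ltr` with at most.  Where the optimal set
realises a count *range*, the conservative end of the observed range is
tested against the favourable end of each replicate's range, making both
reported tails upper bounds; the raw tails at both observed ends are also
reported.  Reports echo their full configuration (mode, replicates, seed,
alpha) and are bit-identical under a fixed seed.

## Time-slicing

A time slice `[first, last]` (closed, on the ordinal stage scale) is
derived in four logged steps: (1) drop terminals whose stratigraphic
range does not intersect the slice, suppressing degree-2 vertices;
(2) date every surviving internal vertex with a minimum-age constraint —
the oldest first-appearance among *all* its descendants in the full tree,
dropped or not, since a divergence is at least as old as the oldest
lineage it subtends (first appearances, not ghost-range midpoints);
(3) dissolve vertices dated strictly before the slice, promoting their
child subtrees to separate clades — the fit machinery scores multiple
clades simultaneously, so out-of-slice divergences are removed without
deleting terminals; a vertex dated exactly at the slice start is
retained; (4) re-apply singleton-area pruning.  Slices retaining fewer
than three terminals or fewer than three represented areas raise rather
than return an unanalysable data-set.

Singleton-area pruning removes terminals whose every listed area is
carried by exactly one terminal (congruence between clades cannot be
assessed for an area seen once).  The rule is applied to a logged
fixpoint; because a pruned terminal's areas were exclusively its own, the
fixpoint is in fact reached in a single pass — the loop and per-pass log
exist so this is auditable.  Areas left unrepresented are dropped from
the universe, and the log records every removal.

## Occupancy

Occurrence records (content code, area, stage) pool into a stage × area
grid of code sets.  The packaged pterosaur compendium transcription spans
26 stages (Carnian–Maastrichtian) × 9 areas = 234 cells with 205 records.
`emptiness_stats` reports the percentage of empty cells under three
rules: none (60% on the packaged transcription), `pti-only` — cells whose
only content is indeterminate pterosaur material count as empty (67%) —
and `pti-or-pdi`, which also discounts indeterminate pterodactyloid
material (70%).  Percentages are rounded to the nearest integer for
reporting; raw fractions are available.  Taxa of uncertain age are
recorded in the oldest possible stage, following the compendium's own
convention.

## Simulator

`simulate` draws (or accepts) a generating area cladogram `H` and grows
each clade by repeated leaf-splitting; every lineage occupies a vertex of
`H`, and each split draws vicariance (internal vertices only; daughters
descend into the two children), sympatry (daughters stay), or dispersal
(one daughter jumps to a uniformly chosen other vertex), with
probabilities renormalised over the permitted events.  After each split
each daughter at an internal vertex steps one edge down with probability
`per_branch_extinction_prob` (default 0.05 — occasional early local
extinction); after growth every lineage still at an internal vertex
descends to a uniformly chosen leaf of its subtree, each skipped edge a
true extinction, so terminals end in a single extant area.  Growth stops
at exactly the requested terminal count (no birth–death timing — only
topology and assignments matter downstream); parameter settings that
cannot realise the requested size (e.g. pure vicariance from a leaf
placement) error after bounded retries.  The generating cladogram, true
event counts and realized assignments are returned as ground truth.

Founding-lineage placement is a parameter because it encodes the
scenario: `leaf` (default) models a sweepstakes coloniser radiating
within one extant area; `root` models a vicariant radiation tracking the
fragmentation of the ancestral composite area; `uniform` is agnostic.

### Validation experiments and their problem sizes

The recovery and calibration experiments (test suite and
`scripts/acceptance.py`) use:

* vicariance recovery — 50 runs of 16 terminals, 1 clade, 4 areas,
  p = (0.8, 0.15, 0.05) for (vic, sym, dis), root placement; dispersal is
  kept rare because it is the process that overwrites vicariant signal.
  Checks: the generating cladogram sits in the MC-optimal set, and the SC
  cost test (pterm, 1,000 replicates) rejects the null, each in a clear
  majority of runs.  MC's own cost test is expectedly non-significant on
  such data (its null can codiverge almost as well), so SC carries the
  rejection check.
* sympatry recovery — 50 runs of 4 clades × 4 terminals, 4 areas,
  p = (0.05, 0.9, 0.05), leaf placement (separate single-area
  radiations); the sympatry `gtr` tail (pterm, 1,000 replicates, first
  optimal cladogram) falls below 0.05 in ≥ 80% of runs.
* type-I calibration — 200 data-sets of 16 terminals with assignments
  drawn independently of topology, tested against one random a-priori
  cladogram each; rejection rate at alpha = 0.05 stays within the
  binomial band [0.02, 0.09].

What the simulator does *not* emulate: fossil sampling and preservation
(every tip is observed), widespread terminals (every simulated tip ends
single-area), stratigraphic ranges, extinction of whole lineages before
the present, and any geographic distance structure on dispersal.  Passing
recovery tests therefore demonstrate the statistical machinery under the
model's own assumptions, not robustness to the sampling pathologies real
fossil data carry.

## Known limitations

* Exhaustive search only (≤ 7 areas); no heuristic area search, no
  constrained/backbone searches, no consensus of optimal cladograms.
* No likelihood-based biogeography (DEC-style models), no time-calibrated
  reconciliation, no distinction between true sympatry and within-area
  allopatry.
* Per-tree permutation p-values for searched optima carry selection
  optimism (see above).
* The packaged occupancy compendium is a transcription of a published
  summary table; its emptiness percentages are reported as computed from
  that transcription.
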