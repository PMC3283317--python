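# Methods

## The evolutionary model

The package models the evolution of a tandemly arrayed gene (TAG) cluster
observed in several genomes. A *state* is an ordered gene tree set: one
rooted binary gene tree whose leaves are the current gene copies, plus one
signed gene order per current genome. A history starts from a single
positive ancestral gene and applies, one at a time:

- **tandem duplication** of a contiguous sub-sequence `(u_p..u_q)`: the
  sub-sequence is replaced by the two adjacent copy blocks
  `(l_p..l_q, r_p..r_q)`, all copies keeping the sign of their original, and
  each leaf `u_x` of the tree is replaced by the cherry `(l_x, r_x)`;
- **inverted duplication**: as above, but one of the two copy blocks is
  reversed and sign-flipped (`(-l_q..-l_p, r_p..r_q)` or
  `(l_p..l_q, -r_q..-r_p)`; the `variant` field records which);
- **inversion**: a sub-sequence is reversed and sign-flipped; the tree is
  unchanged;
- **deletion**: a sub-sequence is removed from the order, its leaves removed
  from the tree with unary-vertex suppression; every removed gene counts as
  one gene loss;
- **speciation**: the full order of one genome is copied into two daughter
  genomes; every leaf of that genome becomes a cherry.

Event costs are affine in the event size *m* (genes touched):
`cost = α_e + m·β_e`, with defaults α = 100 (both duplication types) or 500
(deletion, inversion) and β = 1 everywhere. Duplications being much cheaper
to open than deletions or inversions reflects the expectation that unequal
crossing-over is the dominant mechanism in TAG clusters. Speciations are
free. Event types can be *disabled* (they then carry infinite cost and are
skipped during neighbourhood generation), which is how analyses of clusters
where inversions would be deleterious are configured — no structural change,
just a cost model.

Deleting the last copy in a genome is rejected by default: the model
describes the evolution of an observed cluster, not its extinction. An
`allow_empty_genome` escape hatch exists for deliberately degenerate
replays.

## Single-branch backward search

Inference works on a "history graph" whose vertices are ordered gene trees
and whose edges are events, explored *backwards* from the observed state.
The backward neighbourhoods are:

- **duplication undo**: every window of `2m` contiguous genes that splits
  into two blocks with `(l_x, r_x)` an equal-signed cherry at every position
  collapses to the ancestral segment; each cherry collapse names the new
  leaf after the cherry's internal vertex, so labelling along any backward
  path is deterministic;
- **inverted-duplication undo**: the same with one block reversed and
  sign-flipped, both variants and both child assignments considered;
- **inversion undo**: one predecessor per contiguous span (inversions are
  involutions) — exactly `n(n+1)/2` of them;
- **duplication-with-deletion undo**: a duplication of `m` genes whose copy
  region immediately lost one contiguous run of `d ≤ m−1` copies from one
  copy block. Surviving pairs must form sign-consistent cherries (at least
  one pair anchors the pattern); positions whose partner was deleted keep
  the surviving copy. Restricting the deleted run to a single block keeps
  this neighbourhood quadratic; longer or split deletions arise as chains of
  compound events. Bare deletions are *not* edges of the graph — they would
  make it infinite.

The search itself is a greedy uniform-cost beam: the frontier of partial
backward histories is expanded one graph depth per round and pruned back to
the `queue_capacity` cheapest states (ties broken by a canonical state
order, so runs are bit-reproducible). A state stops expanding once its order
holds the target gene count `g`; rounds continue until no retained partial
history is cheaper than the best solution, so *all* minimum-cost ancestors
reachable through the retained frontier are collected, together with the DAG
of minimum-cost backward paths. With an unbounded queue the procedure is
exact (verified against exhaustive forward enumeration on small instances);
with the default capacity it is a heuristic and the result flags
`overflowed` when pruning fired.

`queue_capacity` defaults to 300. The knob trades accuracy for time and
memory; the default was chosen, during development, as the smallest
capacity that left inferred histories unchanged relative to much larger
queues on the hardest simulated instances profiled (mixed-design clusters
of ~20 genes with deletions), whereas clearly smaller capacities degraded
them. `depth` (rounds between prunings, default 1) and `max_solutions`
(cap on the reported solution set, default 256) are secondary knobs.

## Reconciliation

The gene tree is embedded into the species tree by the standard LCA mapping:
each internal gene vertex maps to the LCA of its children's images and is a
*duplication* when its image equals a child's image (it occurred on the
species branch entering that image), a *speciation* otherwise. Implied
pass-through genes are materialised for every lineage crossing a speciation,
each carrying a loss on the sibling branch. This yields, per species vertex
`A`, the genome set `G(A)` (ancestral gene content), the pre-speciation set
`PG(A) ⊆ G(parent(A))` (genes not lost on the branch entering `A`), the
per-branch loss lists, and the *branch forest*: the reconciled tree
restricted to the branch — one cherry tree per `PG(A)` member whose leaves
are `G(A)` members. The branch forest is exactly the tree structure the
backward search needs on that branch, and reaching `|PG(A)|` genes is
equivalent to collapsing every forest tree to its root. The LCA mapping
minimises duplications plus losses over all reconciliations (tested against
full enumeration); a precomputed reconciliation can be supplied instead.

The gene family is assumed to originate above the species root, i.e. every
extant genome carries at least one family member; inputs violating this are
rejected rather than silently re-rooted.

## Multi-species gluing

The species tree is processed bottom-up. At each internal vertex `A`, for
each child branch: the backward search runs from every element of the
child's solution set up to `|PG|` genes; only orders attained at the branch
minimum `MIN` are kept (per-branch truncation — deliberately greedy, global
optimality is not claimed); the branch's lost genes are reinserted at every
position with either sign (a combinatorial closure of
`(n+k)!/n! · 2^k` orders, guarded by a configurable cap of 10^4 because the
closure is exponential in the loss count); the union over both branches
forms `E(A)`. Speciation edges connect each element of `E(A)` to its
originating order on its own side and to the minimum-ID-distance elements of
the other side's pre-speciation layer (all ties included). Above the species
root the search continues to a single ancestral gene.

Two cost figures are reported, because the choice is genuinely open:
`branch_cost` (the sum of per-branch search minima, the quantity the
per-branch truncation optimises) and `total_cost`, which adds the chosen
speciation edges' ID events converted through the cost model
(`id_plain_labels=True` switches the traceback objective to plain event
counts). Edge *selection* always uses plain ID counts, as the labels are
defined; `id_label_total` reports their sum.

### ID distance

The label of a speciation edge `(x, y)` is the minimum number of inversions
plus deletions transforming `x` into `y`. For `|x| ≤ 8` (configurable) the
value is exact, by breadth-first search over the inversion/deletion state
space in which deletions are only attempted on runs of genes absent from
`y` (such deletions are the only useful ones) and the depth is bounded by a
constructive upper bound. Beyond the bound the upper bound itself is
returned, flagged inexact: delete maximal runs of absent genes, then sort
the remainder by inversions (exact for remainders ≤ 8 genes, greedy
placement beyond), improved by a one- or two-inversion lookahead that can
merge doomed runs before deleting them. Every bound is an explicit event
list, so returned values are always realisable and never undercut the true
distance.

### Traceback and validation

A concrete history is extracted by dynamic programming over the solution
graph: for every candidate at every vertex, the cheapest downstream choice
of speciation edges (ID events costed through the cost model) and
continuations; ties broken lexicographically. The chosen backward paths are
reversed into forward events, speciation-edge labels expanded into explicit
inversion/deletion events, and the whole history replayed forward from a
single gene. Validation compares the replay against the observation under
the position bijection: orders must match genome-by-genome in length and
signs, and the replayed gene tree must be isomorphic to the input gene tree
after renaming. Every inference validates its own traceback; the result
carries the report.

## Simulator

The simulator emulates cluster evolution along a species tree: each branch
(including the lineage above the root speciation) carries an event budget
applied in random order; event sizes are drawn from a geometric distribution
with p = 0.5 truncated and renormalised to the current cluster size
(smaller events are more frequent in real clusters); positions are uniform
among valid spans; the inverted-duplication variant is uniform. Budget
entries that are momentarily infeasible — a deletion on a single-gene
cluster, a fixed-size double duplication before the cluster has two genes —
are deferred behind later growth on the same branch, and an error is raised
if a full pass cannot place them. Three named designs cover the standard
experimental settings (fixed-size duplications for exact gene counts
`3dn+1`; a fixed total of x duplications with 0%, 33% or 50% inversions
spread round-robin over branches; and a mixed design with a deletion of size
1–2 per branch).

What the simulator does *not* emulate: sequence evolution (gene trees are
known exactly, no phylogenetic reconstruction error), branch lengths or rate
heterogeneity, dispersed (non-tandem) duplications, and gene conversion.
Accuracy measured on simulated data therefore isolates the inference
problem itself; with real clusters, gene-tree error is an additional — often
dominant — source of uncertainty, which users can address by running the
inference over a sample of credible gene trees.

## Evaluation experiments and problem sizes

`tagevol.evaluate` measures duplication-count recovery (fixed-total design,
x ∈ {2, 4, 6}, two genomes, 20 replicates per condition) and
size-distribution recovery (mixed design, two genomes, 20 replicates; leaf
clusters of roughly 10–25 genes). Twenty replicates keep a full run at desk
scale on one CPU; both counts are configurable. Only event counts and size
histograms are compared between truth and inference: optimal histories are
highly non-unique, so event-by-event matching would be meaningless. Reports
are pure functions of their seed; per-replicate seeds derive from the
experiment seed through `numpy.random.SeedSequence`.

## Known limitations

- Multiple or clustered gene losses explode the loss-reinsertion closure;
  the cap turns this into an explicit failure rather than an open-ended
  computation.
- The per-branch truncation can discard ancestral orders that would be
  globally cheaper; this mirrors the method's published design.
- The beam search is exact only with an unbounded queue; inversion-heavy
  histories are the known weak spot (they induce a mild overestimation of
  duplication counts).
- Speciation-edge labels beyond the exact ID bound are upper bounds, not
  exact distances.
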