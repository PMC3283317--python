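# tagevol

Parsimony reconstruction of the evolutionary history of **orthologous
tandemly arrayed gene (TAG) clusters** in multiple species.

TAG clusters — runs of adjacent paralogous genes produced by unequal
crossing-over — evolve through tandem duplications (simple or multiple,
direct or inverted), deletions and inversions, punctuated by the speciations
of the species phylogeny. Given

1. a rooted binary **gene tree** for the family,
2. a rooted binary **species tree**, and
3. the observed **signed gene order** of the cluster in each extant genome,

`tagevol` infers a most-parsimonious evolutionary history: the ancestral
gene orders at every speciation, the events on every branch, and a complete
replayable history starting from a single ancestral gene.

## Model and algorithm

A state is an *ordered gene tree* `(T, O)`: a gene tree plus the signed
left-to-right order of its leaf genes. Five events act on states: tandem
duplication of a sub-sequence `(u_p..u_q)` (each leaf `u_x` becomes a cherry
`(l_x, r_x)` and the copy block sits next to the original), inverted tandem
duplication (one copy block reversed and sign-flipped), inversion, deletion
(removed leaves; each removed gene is a gene loss) and speciation (the whole
order is copied into two daughter genomes). An event of type *e* acting on
*m* genes costs `α_e + m·β_e`; the defaults are

| event | α | β |
|---|---|---|
| tandem duplication | 100 | 1 |
| inverted duplication | 100 | 1 |
| deletion | 500 | 1 |
| inversion | 500 | 1 |

Inference glues three ingredients:

- **Reconciliation** (`tagevol.reconcile`): the LCA mapping of the gene tree
  into the species tree gives the ancestral gene content `G(A)` at each
  species vertex, the pre-speciation sets `PG(A)` and the per-branch losses.
- **Backward search** (`tagevol.search`): on each branch, a greedy
  best-first exploration of the history graph *backwards* from the observed
  (or candidate) orders, collapsing cherries until the ancestral gene count
  is reached. Deletions appear only in combination with duplications, which
  keeps the neighbourhoods finite (linear for duplications, quadratic for
  inversions and duplication-with-deletion compounds).
- **Multi-species gluing** (`tagevol.multispecies`): a bottom-up traversal
  that truncates each branch's solutions to the minimum cost, reinserts lost
  genes in every position and sign, unions the two branches into the
  solution set `E(A)`, and labels speciation edges with the minimum
  Inversions+Deletions (ID) distance. A final traceback extracts one
  minimum-cost history, which is validated by forward replay.

A forward simulator (`tagevol.simulate`) generates histories consistent with
a species tree under configurable per-branch event budgets, with event sizes
drawn from a truncated geometric distribution (p = 0.5 by default).

## Worked example

```python
from tagevol import infer_history
from tagevol.io import read_gene_tree, read_species_tree, read_orders
from tagevol.multispecies import branch_event_report

gene_tree = read_gene_tree("((1|a1,2|a2),(1|b1,2|b2));")
species_tree = read_species_tree("(1,2)A;")
orders = read_orders(__import__("io").StringIO("1\t+a1 +b1\n2\t+a2 +b2\n"))

result = infer_history(gene_tree, orders, species_tree)
print(result.solution_sets["A"])   # ancestral order(s) at the root speciation
print(result.branch_cost, result.id_label_total, result.validation.ok)
print(branch_event_report(result.history))
```

prints

```
[(('n1', 1), ('n2', 1))]
101.0 0 True
  branch  dup  idup  inv  del  gene_losses
0      A    1     0    0    0            0
```

Both genomes carry the congruent two-gene cluster `(+a, +b)`, so the
ancestral order at the root speciation `A` is a two-gene cluster `(+u, +v)`
and the whole history is one simple tandem duplication (cost
`α_dup + 1·β_dup = 101`) on the lineage above `A`, followed by the
speciation. All speciation-edge ID labels are 0 and the traced-back history
replays exactly to the observed orders.

The same pipeline is available from a shell:

```sh
tagevol simulate --design fig7 --leaves 2 --seed 1 --out-dir sim/
tagevol infer --gene-tree sim/gene_tree.nwk --species-tree sim/species.nwk \
              --orders sim/orders.tsv --out-dir inferred/
tagevol reconcile --gene-tree sim/gene_tree.nwk --species-tree sim/species.nwk
```

`tagevol infer --disable-events inv,idup` restricts the model to
duplications and deletions (appropriate for clusters in which inversions
would be deleterious, e.g. tandem arrays sharing constant downstream exons).

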