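"""Gene-tree / species-tree reconciliation by LCA mapping.

Reconciliation embeds the gene tree into the species tree, explaining their
incongruence by (general) duplications and losses.  Each internal gene-tree
vertex maps to the lowest common ancestor of its children's images; a vertex
is a *duplication* when its image equals a child's image (it occurred on the
species branch entering that image) and a *speciation* otherwise (it is an
ancestral gene present at that species vertex).  The LCA mapping minimises
both the duplication and the loss count over all reconciliations.

From the embedding we derive, for every species vertex ``A``:

- the genome set ``G(A)``: ancestral genes present at the speciation ``A``
  (real speciation vertices mapped to ``A`` plus implied pass-through genes
  for lineages crossing ``A``),
- the pre-speciation set ``PG(A)``: the genes of ``G(parent(A))`` that are
  not lost on the branch entering ``A``,
- the losses on each branch, and
- the *branch forest*: the reconciled tree restricted to the branch, one
  cherry tree per member of ``PG(A)`` whose leaves are the members of
  ``G(A)`` -- exactly the structure the backward search needs to collapse a
  branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from tagevol.model import (
    GeneTree,
    ModelError,
    Node,
    SpeciesTree,
    is_leaf,
    iter_nodes,
    node_children,
    node_label,
)

__all__ = [
    "Reconciliation",
    "lca_reconcile",
    "losses_on_branch",
    "ancestral_gene_count",
]


@dataclass
class Reconciliation:
    """Embedded LCA mapping of a gene tree into a species tree."""

    gene_tree: GeneTree
    species_tree: SpeciesTree
    mapping: dict[str, str]  # gene vertex label -> species vertex
    kinds: dict[str, str]  # gene vertex label -> 'leaf' | 'dup' | 'spec'
    genome_sets: dict[str, tuple[str, ...]]  # A -> G(A) member ids
    pre_speciation_sets: dict[str, tuple[str, ...]]  # A (non-root) -> PG(A)
    losses: dict[tuple[str, str], tuple[str, ...]]  # (B, A) -> lost members of G(B)
    branch_forests: dict[str, frozenset]  # A -> forest of the branch entering A
    branch_root_maps: dict[str, dict[str, str]]  # A -> node label -> PG(A) id
    duplication_count: int = 0
    loss_count: int = 0

    def report_frame(self):
        """Per-vertex summary table: |G(A)|, |PG(A)| and loss lists."""
        import pandas as pd

        parent = self.species_tree.parent_map()
        rows = []
        for a in self.species_tree.postorder():
            rows.append(
                {
                    "species_vertex": a,
                    "is_leaf": self.species_tree.is_leaf(a),
                    "n_genes": len(self.genome_sets[a]),
                    "n_pre_speciation": (
                        len(self.pre_speciation_sets[a]) if a in parent else None
                    ),
                    "losses_on_branch": ",".join(
                        self.losses.get((parent[a], a), ())
                    )
                    if a in parent
                    else "",
                }
            )
        return pd.DataFrame(rows)


def _implied_id(child_label: str, species_vertex: str) -> str:
    return f"{child_label}@{species_vertex}"


def lca_reconcile(gene_tree: GeneTree, species_tree: SpeciesTree) -> Reconciliation:
    """Standard LCA reconciliation with the embedded representation.

    Every gene-tree leaf's genome must be a species-tree leaf and every
    extant genome must carry at least one gene (the gene family is assumed to
    originate above the species root).
    """
    st = species_tree
    parent = st.parent_map()
    depth = st.depth_map()

    def lca(a: str, b: str) -> str:
        while a != b:
            if depth[a] < depth[b]:
                b = parent[b]
            else:
                a = parent[a]
        return a

    def is_ancestor(a: str, b: str) -> bool:
        """a is an ancestor of (or equal to) b."""
        while depth[b] > depth[a]:
            b = parent[b]
        return a == b

    # --- vertex maps -------------------------------------------------------
    labels: set[str] = set()
    mapping: dict[str, str] = {}
    kinds: dict[str, str] = {}
    children_of: dict[str, tuple[Node, Node]] = {}

    def walk(n: Node) -> str:
        lab = node_label(n)
        if lab in labels:
            raise ModelError(f"gene-tree vertex labels must be unique ({lab!r})")
        labels.add(lab)
        if is_leaf(n):
            genome = gene_tree.leaf_genomes[n]
            if genome not in depth or not st.is_leaf(genome):
                raise ModelError(f"genome {genome!r} is not a species-tree leaf")
            mapping[lab] = genome
            kinds[lab] = "leaf"
            return lab
        kids = node_children(n)
        children_of[lab] = kids
        imgs = [mapping[walk(k)] for k in kids]
        m = lca(imgs[0], imgs[1])
        mapping[lab] = m
        kinds[lab] = "dup" if m in imgs else "spec"
        return lab

    root_label = walk(gene_tree.root)
    if mapping[root_label] != st.root:
        raise ModelError(
            "the gene family does not reach the species root "
            "(every extant genome needs at least one gene)"
        )

    # --- genome sets, losses ----------------------------------------------
    genome_sets: dict[str, list[str]] = {a: [] for a in st.postorder()}
    losses: dict[tuple[str, str], list[str]] = {}
    # survives[(member id at B, child D)] marks continuation into branch (B, D)
    survives: set[tuple[str, str]] = set()
    # member id -> ('node', gene vertex label) | ('edge', child endpoint label)
    member_origin: dict[str, tuple[str, str]] = {}

    for lab, kind in kinds.items():
        if kind == "spec":
            a = mapping[lab]
            genome_sets[a].append(lab)
            member_origin[lab] = ("node", lab)
            for kid in children_of[lab]:
                kid_img = mapping[node_label(kid)]
                # the child lineage enters the child branch of a containing kid_img
                for d in st.children[a]:
                    if is_ancestor(d, kid_img):
                        survives.add((lab, d))
        elif kind == "leaf":
            genome_sets[mapping[lab]].append(lab)

    # implied pass-through members: lineages crossing a speciation
    def edge_crossings(u_lab: str | None, c: Node) -> None:
        c_lab = node_label(c)
        bottom = mapping[c_lab]
        if u_lab is None:
            return  # nothing above the gene root: the family originates there
        top = mapping[u_lab]
        # species vertices crossed by the edge (u, c)
        crossed = []
        x = bottom
        while x != top:
            x = parent[x]
            if x != top or kinds[u_lab] == "dup":
                if x != bottom:
                    crossed.append(x)
        # walk from top of the edge downwards
        for x in crossed:
            member = _implied_id(c_lab, x)
            genome_sets[x].append(member)
            member_origin[member] = ("edge", c_lab)
            # continues towards bottom; lost on the other child branch
            for d in st.children[x]:
                if is_ancestor(d, bottom):
                    survives.add((member, d))

    def visit_edges(n: Node, up: str | None) -> None:
        lab = node_label(n)
        edge_crossings(up, n)
        for kid in node_children(n):
            visit_edges(kid, lab)

    visit_edges(gene_tree.root, None)

    genome_sets_t = {a: tuple(sorted(v)) for a, v in genome_sets.items()}

    pre_speciation_sets: dict[str, tuple[str, ...]] = {}
    losses_t: dict[tuple[str, str], tuple[str, ...]] = {}
    for b, kids in st.children.items():
        for a in kids:
            pg = tuple(m for m in genome_sets_t[b] if (m, a) in survives)
            pre_speciation_sets[a] = pg
            losses_t[(b, a)] = tuple(m for m in genome_sets_t[b] if (m, a) not in survives)

    # --- branch forests ----------------------------------------------------
    def build_down(c: Node, level: str) -> Node:
        """Forest node for the lineage of the edge arriving at species vertex
        ``level`` through the gene-tree child endpoint ``c``."""
        c_lab = node_label(c)
        img = mapping[c_lab]
        if img != level:
            return _implied_id(c_lab, level)  # edge crosses this speciation
        if kinds[c_lab] in ("leaf", "spec"):
            return c_lab
        # duplication on the branch entering `level`
        kids = node_children(c)
        return ("N", c_lab, frozenset(build_down(k, level) for k in kids))

    branch_forests: dict[str, frozenset] = {}
    branch_root_maps: dict[str, dict[str, str]] = {}

    # locate gene vertices by label for PG roots
    node_by_label: dict[str, Node] = {}
    for n in iter_nodes(gene_tree.root):
        node_by_label[node_label(n)] = n

    for b, kids in st.children.items():
        for a in kids:
            roots: list[tuple[str, Node]] = []
            for member in pre_speciation_sets[a]:
                origin_kind, lab = member_origin[member]
                if origin_kind == "edge":
                    # implied member: the same gene edge continues downwards
                    roots.append((member, build_down(node_by_label[lab], a)))
                else:
                    v = node_by_label[lab]  # real speciation vertex at b
                    for kid in node_children(v):
                        if is_ancestor(a, mapping[node_label(kid)]):
                            roots.append((member, build_down(kid, a)))
            forest = frozenset(node for _, node in roots)
            if len(forest) != len(roots):
                raise ModelError("branch forest trees are not distinct")
            branch_forests[a] = forest
            branch_root_maps[a] = {
                node_label(sub): pg_id
                for pg_id, node in roots
                for sub in iter_nodes(node)
            }

    # pre-root branch: the whole family coalesces into the single gene root
    root_node = gene_tree.root
    pre_root = build_down(root_node, st.root)
    branch_forests[st.root] = frozenset({pre_root})
    branch_root_maps[st.root] = {
        node_label(sub): root_label for sub in iter_nodes(pre_root)
    }

    dup_count = sum(1 for k in kinds.values() if k == "dup")
    loss_count = sum(len(v) for v in losses_t.values())

    return Reconciliation(
        gene_tree=gene_tree,
        species_tree=st,
        mapping=mapping,
        kinds=kinds,
        genome_sets=genome_sets_t,
        pre_speciation_sets=pre_speciation_sets,
        losses=losses_t,
        branch_forests=branch_forests,
        branch_root_maps=branch_root_maps,
        duplication_count=dup_count,
        loss_count=loss_count,
    )


def losses_on_branch(rec: Reconciliation, branch: tuple[str, str]) -> tuple[str, ...]:
    """Ancestral genes of ``G(B)`` lost on the branch ``(B, A)``."""
    if branch not in rec.losses:
        raise ModelError(f"no branch {branch} in the species tree")
    return rec.losses[branch]


def ancestral_gene_count(rec: Reconciliation, species_vertex: str) -> int:
    """``|G(A)|`` -- the inferred gene count at an internal species vertex."""
    if rec.species_tree.is_leaf(species_vertex):
        raise ModelError(
            "gene counts at extant genomes come from the observed order, "
            "not the reconciliation"
        )
    return len(rec.genome_sets[species_vertex])
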