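"""File formats: Newick trees, signed-order TSV, history TSV.

Gene-tree leaf labels encode the genome and the gene as ``<genome>|<gene>``
(the separator is configurable).  Orders files are TSV with one line per
genome: the genome identifier, a tab, then space-separated signed gene ids
such as ``+a -b +c``.
"""

from __future__ import annotations

import io as _io
import sys
import warnings
from typing import Mapping, TextIO

import dendropy

from tagevol.model import (
    Event,
    GeneOrder,
    GeneTree,
    History,
    ModelError,
    Node,
    Order,
    SpeciesTree,
    is_leaf,
    iter_nodes,
    node_children,
    node_label,
)

__all__ = [
    "read_gene_tree",
    "read_species_tree",
    "read_orders",
    "write_orders",
    "write_newick",
    "gene_tree_newick",
    "species_tree_newick",
    "write_history",
    "read_history_events",
]

SEPARATOR = "|"


def _parse_newick(source: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=source, schema="newick")
    for nd in tree.preorder_node_iter():
        n_children = len(nd.child_nodes())
        if n_children not in (0, 2):
            raise ModelError(
                f"tree must be rooted and binary (vertex with {n_children} children)"
            )
    return tree


def read_gene_tree(source: str | TextIO, separator: str = SEPARATOR) -> GeneTree:
    """Parse a rooted binary gene tree whose leaf labels are
    ``<genome><separator><gene>``.  Unlabelled internal vertices receive
    deterministic labels ``n1, n2, ...`` in postorder."""
    text = source.read() if hasattr(source, "read") else source
    try:
        text = open(text).read() if "\n" not in text and "(" not in text else text
    except OSError:
        pass
    tree = _parse_newick(text)
    leaf_genomes: dict[str, str] = {}
    counter = [0]
    used: set[str] = set()

    def conv(nd) -> Node:
        kids = nd.child_nodes()
        if not kids:
            label = nd.taxon.label if nd.taxon else nd.label
            if label is None or separator not in label:
                raise ModelError(
                    f"gene-tree leaf label {label!r} must be "
                    f"'<genome>{separator}<gene>'"
                )
            genome, gene = label.split(separator, 1)
            if gene in leaf_genomes:
                raise ModelError(f"duplicate gene id {gene!r}")
            leaf_genomes[gene] = genome
            used.add(gene)
            return gene
        a, b = (conv(k) for k in kids)
        label = nd.label
        if not label:
            counter[0] += 1
            label = f"n{counter[0]}"
        if label in used:
            raise ModelError(f"duplicate internal label {label!r}")
        used.add(label)
        return ("N", label, frozenset((a, b)))

    root = conv(tree.seed_node)
    return GeneTree(root=root, leaf_genomes=leaf_genomes)


def read_species_tree(source: str | TextIO) -> SpeciesTree:
    """Parse a rooted binary species tree; unlabelled internal vertices get
    deterministic labels ``A1, A2, ...`` in postorder."""
    text = source.read() if hasattr(source, "read") else source
    try:
        text = open(text).read() if "\n" not in text and "(" not in text else text
    except OSError:
        pass
    tree = _parse_newick(text)
    children: dict[str, tuple[str, str]] = {}
    counter = [0]
    used: set[str] = set()

    def conv(nd) -> str:
        kids = nd.child_nodes()
        if not kids:
            label = nd.taxon.label if nd.taxon else nd.label
            if not label:
                raise ModelError("species-tree leaves must be labelled")
        else:
            label = nd.label
            if not label:
                counter[0] += 1
                label = f"A{counter[0]}"
        if label in used:
            raise ModelError(f"duplicate species label {label!r}")
        used.add(label)
        if kids:
            a, b = (conv(k) for k in kids)
            children[label] = (a, b)
        return label

    root = conv(tree.seed_node)
    return SpeciesTree(root=root, children=children)


def read_orders(source: str | TextIO) -> dict[str, Order]:
    """Read signed gene orders (TSV, one genome per line)."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = open(source).read()
    orders: dict[str, Order] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        if "\t" not in line:
            raise ModelError(f"orders line {lineno}: expected '<genome>\\t<genes>'")
        genome, rest = line.split("\t", 1)
        genome = genome.strip()
        if genome in orders:
            raise ModelError(f"orders line {lineno}: duplicate genome {genome!r}")
        genes: list[tuple[str, int]] = []
        for tok in rest.split():
            if tok[0] == "+":
                genes.append((tok[1:], 1))
            elif tok[0] == "-":
                genes.append((tok[1:], -1))
            else:
                raise ModelError(
                    f"orders line {lineno}: token {tok!r} is missing its sign"
                )
        if not genes:
            warnings.warn(
                f"genome {genome!r} has an empty order (all copies lost?)",
                stacklevel=2,
            )
        GeneOrder(genome=genome, genes=tuple(genes))  # validates
        orders[genome] = tuple(genes)
    return orders


def write_orders(orders: Mapping[str, Order], out: TextIO | str) -> None:
    close = False
    if not hasattr(out, "write"):
        out, close = open(out, "w"), True
    try:
        for genome in sorted(orders):
            genes = " ".join(
                f"{'+' if s > 0 else '-'}{g}" for g, s in orders[genome]
            )
            out.write(f"{genome}\t{genes}\n")
    finally:
        if close:
            out.close()


def _node_newick(node: Node, leaf_fmt) -> str:
    if is_leaf(node):
        return leaf_fmt(node)
    kids = sorted((_node_newick(k, leaf_fmt) for k in node_children(node)))
    return f"({','.join(kids)}){node_label(node)}"


def gene_tree_newick(tree: GeneTree, separator: str = SEPARATOR) -> str:
    return (
        _node_newick(tree.root, lambda g: f"{tree.leaf_genomes[g]}{separator}{g}")
        + ";"
    )


def species_tree_newick(st: SpeciesTree) -> str:
    def fmt(v: str) -> str:
        if st.is_leaf(v):
            return v
        a, b = st.children[v]
        return f"({fmt(a)},{fmt(b)}){v}"

    return fmt(st.root) + ";"


def write_newick(text: str, out: TextIO | str) -> None:
    if hasattr(out, "write"):
        out.write(text + "\n")
    else:
        with open(out, "w") as fh:
            fh.write(text + "\n")


_HIST_COLS = (
    "branch\tgenome\ttype\tp\tq\tvariant\tdel_p\tdel_q\tchild_left\tchild_right"
)


def write_history(history: History, out: TextIO | str) -> None:
    """One event per row: branch, genome, type, span, variant, deleted
    sub-span and speciation daughters."""
    close = False
    if not hasattr(out, "write"):
        out, close = open(out, "w"), True
    try:
        out.write(_HIST_COLS + "\n")
        for ev in history.events:
            p, q = ev.span if ev.span else ("", "")
            dp, dq = ev.deleted_subspan if ev.deleted_subspan else ("", "")
            cl, cr = ev.children if ev.children else ("", "")
            out.write(
                f"{ev.branch or ''}\t{ev.genome}\t{ev.etype}\t{p}\t{q}\t"
                f"{ev.variant or ''}\t{dp}\t{dq}\t{cl}\t{cr}\n"
            )
    finally:
        if close:
            out.close()


def read_history_events(source: str | TextIO) -> list[Event]:
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = open(source).read()
    lines = text.splitlines()
    if not lines or lines[0] != _HIST_COLS:
        raise ModelError("unrecognised history file header")
    events = []
    for line in lines[1:]:
        if not line.strip():
            continue
        branch, genome, etype, p, q, variant, dp, dq, cl, cr = line.split("\t")
        events.append(
            Event(
                etype,
                genome,
                (int(p), int(q)) if p else None,
                variant=variant or None,
                deleted_subspan=(int(dp), int(dq)) if dp else None,
                children=(cl, cr) if cl else None,
                branch=branch or None,
            )
        )
    return events
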