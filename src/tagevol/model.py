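"""Core domain types and forward semantics of the evolutionary model.

A *state* of the model is an ordered gene tree set: a rooted binary gene tree
together with one signed gene order per current genome.  Five event types act
on a state:

- ``dup``   tandem duplication of a contiguous sub-sequence; every duplicated
            leaf is replaced by a cherry of two new copies, both copies keep
            the sign of the original, and the copy block is placed directly
            after the original block;
- ``idup``  inverted tandem duplication: as ``dup`` but one of the two copy
            blocks (the ``variant`` side) is reversed and sign-flipped;
- ``inv``   inversion: a contiguous sub-sequence is reversed and sign-flipped,
            the tree is unchanged;
- ``del``   deletion: a contiguous sub-sequence is removed from the order and
            its leaves are removed from the tree (each removed gene is a gene
            loss), unary vertices being suppressed;
- ``spec``  speciation: the whole order of a genome is copied into two
            daughter genomes and every leaf of that genome is replaced by a
            cherry.

Gene trees are stored as immutable nested nodes so that states can be hashed
and compared structurally: a leaf is its gene id (a string) and an internal
vertex is ``("N", label, frozenset({child, child}))``.  Child sets are
unordered, mirroring the fact that the model does not orient cherries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Iterator, Mapping, Sequence

Sign = int  # +1 or -1
SGene = tuple[str, Sign]  # (gene id, sign)
Order = tuple[SGene, ...]

EVENT_TYPES = ("dup", "idup", "inv", "del", "spec")
#: label_factory signature: gene id -> (left copy id, right copy id)
LabelFactory = Callable[[str], tuple[str, str]]


class ModelError(ValueError):
    """Raised on invalid events, spans or malformed states."""


# ---------------------------------------------------------------------------
# nested tree nodes
# ---------------------------------------------------------------------------

Node = object  # str (leaf) | ("N", label, frozenset({Node, Node}))


def internal(label: str, a: Node, b: Node) -> Node:
    return ("N", label, frozenset((a, b)))


def is_leaf(node: Node) -> bool:
    return isinstance(node, str)


def node_label(node: Node) -> str:
    return node if isinstance(node, str) else node[1]


def node_children(node: Node) -> tuple[Node, ...]:
    return () if isinstance(node, str) else tuple(node[2])


def iter_leaves(node: Node) -> Iterator[str]:
    stack = [node]
    while stack:
        n = stack.pop()
        if isinstance(n, str):
            yield n
        else:
            stack.extend(n[2])


def iter_nodes(node: Node) -> Iterator[Node]:
    """All nodes of the subtree, parents before children."""
    stack = [node]
    while stack:
        n = stack.pop()
        yield n
        if not isinstance(n, str):
            stack.extend(n[2])


def replace_leaves(node: Node, mapping: Mapping[str, Node]) -> Node:
    """Substitute whole subtrees for the leaves named in ``mapping``."""
    if isinstance(node, str):
        return mapping.get(node, node)
    _, label, kids = node
    return ("N", label, frozenset(replace_leaves(k, mapping) for k in kids))


def remove_leaves(node: Node, dead: frozenset) -> Node | None:
    """Remove leaves and suppress resulting unary vertices.

    Returns ``None`` when every leaf of the subtree is removed.
    """
    if isinstance(node, str):
        return None if node in dead else node
    _, label, kids = node
    kept = [c for c in (remove_leaves(k, dead) for k in kids) if c is not None]
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]  # suppression: the label of the unary vertex vanishes
    return ("N", label, frozenset(kept))


def cherries(node: Node) -> dict[str, tuple[str, str]]:
    """Map leaf -> (sibling leaf, parent label) for every cherry of the tree."""
    out: dict[str, tuple[str, str]] = {}
    for n in iter_nodes(node):
        if not isinstance(n, str):
            kids = tuple(n[2])
            if len(kids) == 2 and isinstance(kids[0], str) and isinstance(kids[1], str):
                a, b = kids
                out[a] = (b, n[1])
                out[b] = (a, n[1])
    return out


def collapse_cherries(node: Node, parents: frozenset) -> Node:
    """Collapse every cherry whose parent label is in ``parents`` to a leaf
    carrying the parent's label."""
    if isinstance(node, str):
        return node
    _, label, kids = node
    kids = tuple(kids)
    if (
        label in parents
        and len(kids) == 2
        and isinstance(kids[0], str)
        and isinstance(kids[1], str)
    ):
        return label
    return ("N", label, frozenset(collapse_cherries(k, parents) for k in kids))


def topo_signature(node: Node, leaf_map: Mapping[str, object] | None = None):
    """Canonical label-free topology of a subtree (leaf names optionally
    translated through ``leaf_map``); used for isomorphism checks."""
    if isinstance(node, str):
        return ("L", leaf_map[node] if leaf_map is not None else node)
    return frozenset(topo_signature(k, leaf_map) for k in node[2])


# ---------------------------------------------------------------------------
# domain dataclasses
# ---------------------------------------------------------------------------


class SignedGene:
    """A gene copy with an orientation.  Stored as plain ``(id, sign)`` tuples
    throughout the package; this constructor only validates and normalises."""

    __slots__ = ()

    def __new__(cls, gene_id: str, sign: int) -> SGene:  # type: ignore[misc]
        if sign not in (1, -1):
            raise ModelError(f"sign must be +1 or -1, got {sign!r}")
        return (gene_id, sign)


@dataclass(frozen=True)
class GeneOrder:
    """The signed left-to-right order of the cluster members in one genome."""

    genome: str
    genes: Order

    def __post_init__(self) -> None:
        ids = [g for g, _ in self.genes]
        if len(set(ids)) != len(ids):
            raise ModelError(f"duplicate gene ids in order of genome {self.genome}")
        for _, s in self.genes:
            if s not in (1, -1):
                raise ModelError("gene signs must be +1 or -1")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class GeneTree:
    """A rooted binary gene tree plus the genome each extant leaf belongs to."""

    root: Node
    leaf_genomes: Mapping[str, str]

    def __post_init__(self) -> None:
        leaves = set(iter_leaves(self.root))
        if leaves != set(self.leaf_genomes):
            raise ModelError("leaf_genomes keys must equal the tree's leaf set")
        for n in iter_nodes(self.root):
            if not isinstance(n, str) and len(n[2]) != 2:
                raise ModelError("gene tree must be binary")

    @property
    def leaves(self) -> frozenset:
        return frozenset(iter_leaves(self.root))


@dataclass(frozen=True)
class SpeciesTree:
    """Rooted binary species tree; vertices are genome identifiers."""

    root: str
    children: Mapping[str, tuple[str, str]]  # internal vertex -> (left, right)

    def __post_init__(self) -> None:
        seen: set[str] = set()

        def walk(v: str) -> None:
            if v in seen:
                raise ModelError(f"repeated species-tree vertex {v!r}")
            seen.add(v)
            for c in self.children.get(v, ()):
                walk(c)

        walk(self.root)
        if seen != {self.root} | {c for kids in self.children.values() for c in kids}:
            raise ModelError("species tree children map is inconsistent")

    def is_leaf(self, v: str) -> bool:
        return v not in self.children

    @property
    def leaves(self) -> tuple[str, ...]:
        return tuple(v for v in self.postorder() if self.is_leaf(v))

    def parent_map(self) -> dict[str, str]:
        return {c: v for v, kids in self.children.items() for c in kids}

    def postorder(self) -> Iterator[str]:
        def walk(v: str) -> Iterator[str]:
            for c in self.children.get(v, ()):
                yield from walk(c)
            yield v

        return walk(self.root)

    def depth_map(self) -> dict[str, int]:
        out = {self.root: 0}
        stack = [(self.root, 0)]
        while stack:
            v, d = stack.pop()
            out[v] = d
            for c in self.children.get(v, ()):
                stack.append((c, d + 1))
        return out


@dataclass(frozen=True)
class OrderedGeneTreeSet:
    """A gene tree together with one signed gene order per current genome."""

    tree: Node
    orders: Mapping[str, Order]  # genome -> order

    def __post_init__(self) -> None:
        in_orders = [g for o in self.orders.values() for g, _ in o]
        if len(set(in_orders)) != len(in_orders):
            raise ModelError("a gene id occurs in two orders")
        if set(in_orders) != set(iter_leaves(self.tree)):
            raise ModelError("tree leaves and order contents differ")

    def genome_of(self) -> dict[str, str]:
        return {g: gm for gm, o in self.orders.items() for g, _ in o}

    def gene_count(self) -> int:
        return sum(len(o) for o in self.orders.values())

    def key(self):
        """Hashable canonical identity (genomes sorted)."""
        return (tuple(sorted(self.orders.items())), self.tree)


def single_gene_state(gene_id: str = "g", genome: str = "0", sign: Sign = 1) -> OrderedGeneTreeSet:
    """The origin of every history: one positive ancestral gene."""
    return OrderedGeneTreeSet(tree=gene_id, orders={genome: ((gene_id, sign),)})


# ---------------------------------------------------------------------------
# events and costs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Event:
    """One evolutionary event.

    ``span`` is 1-based inclusive ``(p, q)`` on the order of ``genome`` at the
    time the event is applied.  ``deleted_subspan`` turns a (inverted)
    duplication into a compound duplication-with-deletion: after the copy
    blocks are laid out, the genes at those 1-based positions (which must fall
    inside the fresh copy region) are deleted again.  ``children`` names the
    two daughter genomes of a speciation.  ``branch`` optionally records the
    species-tree branch the event belongs to (identified by the branch's lower
    vertex).
    """

    etype: str
    genome: str
    span: tuple[int, int] | None = None
    variant: str | None = None  # 'left' | 'right' for idup
    deleted_subspan: tuple[int, int] | None = None
    children: tuple[str, str] | None = None
    branch: str | None = None

    def __post_init__(self) -> None:
        if self.etype not in EVENT_TYPES:
            raise ModelError(f"unknown event type {self.etype!r}")
        if self.etype == "spec":
            if self.span is not None:
                raise ModelError("speciation events carry no span")
            if self.children is None:
                raise ModelError("speciation events must name the daughter genomes")
        else:
            if self.span is None:
                raise ModelError(f"{self.etype} event requires a span")
            p, q = self.span
            if not (1 <= p <= q):
                raise ModelError(f"invalid span {self.span}")
        if self.deleted_subspan is not None and self.etype not in ("dup", "idup"):
            raise ModelError("deleted_subspan is only valid on dup/idup events")
        if self.etype == "idup" and self.variant not in ("left", "right"):
            raise ModelError("idup events need variant 'left' or 'right'")

    @property
    def size(self) -> int:
        if self.span is None:
            return 0
        return self.span[1] - self.span[0] + 1

    @property
    def del_size(self) -> int:
        if self.deleted_subspan is None:
            return 0
        return self.deleted_subspan[1] - self.deleted_subspan[0] + 1


@dataclass(frozen=True)
class CostModel:
    """Affine event costs ``alpha_e + m * beta_e``.

    Disabled event types carry infinite cost (and are skipped during
    neighbourhood generation) rather than being structurally absent, so that
    constrained analyses -- e.g. clusters where inversions would be
    deleterious -- are a pure cost-model change.  Speciations are free.
    """

    alpha: Mapping[str, float]
    beta: Mapping[str, float]
    enabled: frozenset = frozenset({"dup", "idup", "inv", "del"})

    def __post_init__(self) -> None:
        for t in ("dup", "idup", "inv", "del"):
            if self.alpha.get(t, 0) < 0 or self.beta.get(t, 0) < 0:
                raise ModelError("costs must be nonnegative")
            if t in self.enabled and self.alpha[t] + self.beta[t] <= 0:
                raise ModelError(f"enabled event type {t} must have positive cost")

    def is_enabled(self, etype: str) -> bool:
        return etype == "spec" or etype in self.enabled

    def cost(self, etype: str, size: int) -> float:
        if etype == "spec":
            return 0.0
        if etype not in self.enabled:
            return math.inf
        if size < 1:
            raise ModelError("events act on at least one gene")
        return self.alpha[etype] + size * self.beta[etype]


#: Default opening/extension costs: duplications are cheap to open relative to
#: deletions and inversions, and every extra gene in a segment costs 1.
DEFAULT_COSTS = CostModel(
    alpha={"dup": 100.0, "idup": 100.0, "del": 500.0, "inv": 500.0},
    beta={"dup": 1.0, "idup": 1.0, "del": 1.0, "inv": 1.0},
)


def event_cost(event: Event, costs: CostModel = DEFAULT_COSTS) -> float:
    """Cost of one event: ``alpha_e + m*beta_e``; a duplication-with-deletion
    compound adds the deletion cost of the deleted sub-span."""
    if event.etype == "spec":
        return 0.0
    c = costs.cost(event.etype, event.size)
    if event.deleted_subspan is not None:
        c += costs.cost("del", event.del_size)
    return c


def history_cost(events: Iterable[Event], costs: CostModel = DEFAULT_COSTS) -> float:
    return sum(event_cost(e, costs) for e in events)


# ---------------------------------------------------------------------------
# forward semantics
# ---------------------------------------------------------------------------


def default_label_factory(gene_id: str) -> tuple[str, str]:
    """Deterministic copy naming: children of ``u`` are ``u.1`` and ``u.2``."""
    return f"{gene_id}.1", f"{gene_id}.2"


def _check_span(order: Order, span: tuple[int, int], genome: str) -> None:
    p, q = span
    if not (1 <= p <= q <= len(order)):
        raise ModelError(
            f"span {span} out of range for genome {genome!r} of length {len(order)}"
        )


def apply_event(
    state: OrderedGeneTreeSet,
    event: Event,
    label_factory: LabelFactory = default_label_factory,
    allow_empty_genome: bool = False,
) -> OrderedGeneTreeSet:
    """Apply one forward event and return the new state.

    ``allow_empty_genome`` permits a deletion that wipes out a genome's whole
    cluster; by default this degenerate situation is rejected because the model
    describes the evolution of an existing cluster, not its extinction.
    """
    if event.genome not in state.orders:
        raise ModelError(f"unknown genome {event.genome!r}")
    order = state.orders[event.genome]
    et = event.etype

    if et == "inv":
        _check_span(order, event.span, event.genome)
        p, q = event.span
        seg = tuple((g, -s) for g, s in reversed(order[p - 1 : q]))
        new_order = order[: p - 1] + seg + order[q:]
        new_orders = dict(state.orders)
        new_orders[event.genome] = new_order
        return OrderedGeneTreeSet(tree=state.tree, orders=new_orders)

    if et == "del":
        _check_span(order, event.span, event.genome)
        p, q = event.span
        dead = frozenset(g for g, _ in order[p - 1 : q])
        new_order = order[: p - 1] + order[q:]
        if not new_order and not allow_empty_genome:
            raise ModelError(
                f"deletion would empty genome {event.genome!r} "
                "(pass allow_empty_genome=True to permit)"
            )
        tree = remove_leaves(state.tree, dead)
        if tree is None:
            raise ModelError("deletion removed the entire gene family")
        new_orders = dict(state.orders)
        if new_order:
            new_orders[event.genome] = new_order
        else:
            del new_orders[event.genome]
        return OrderedGeneTreeSet(tree=tree, orders=new_orders)

    if et in ("dup", "idup"):
        _check_span(order, event.span, event.genome)
        p, q = event.span
        seg = order[p - 1 : q]
        lefts, rights, mapping = [], [], {}
        for g, s in seg:
            l_id, r_id = label_factory(g)
            lefts.append((l_id, s))
            rights.append((r_id, s))
            mapping[g] = internal(g, l_id, r_id)
        if et == "dup":
            block = tuple(lefts) + tuple(rights)
        elif event.variant == "left":
            block = tuple((g, -s) for g, s in reversed(lefts)) + tuple(rights)
        else:  # right
            block = tuple(lefts) + tuple((g, -s) for g, s in reversed(rights))
        new_order = order[: p - 1] + block + order[q:]
        tree = replace_leaves(state.tree, mapping)
        new_orders = dict(state.orders)
        new_orders[event.genome] = new_order
        mid = OrderedGeneTreeSet(tree=tree, orders=new_orders)
        if event.deleted_subspan is not None:
            a, b = event.deleted_subspan
            if not (p <= a <= b <= p + 2 * len(seg) - 1):
                raise ModelError(
                    "deleted_subspan must fall inside the freshly copied region"
                )
            mid = apply_event(
                mid,
                Event("del", event.genome, (a, b)),
                label_factory,
                allow_empty_genome,
            )
        return mid

    # speciation
    gl, gr = event.children
    if gl in state.orders or gr in state.orders:
        raise ModelError("daughter genome identifier already in use")
    lefts, rights, mapping = [], [], {}
    for g, s in order:
        l_id, r_id = label_factory(g)
        lefts.append((l_id, s))
        rights.append((r_id, s))
        mapping[g] = internal(g, l_id, r_id)
    tree = replace_leaves(state.tree, mapping)
    new_orders = dict(state.orders)
    del new_orders[event.genome]
    new_orders[gl] = tuple(lefts)
    new_orders[gr] = tuple(rights)
    return OrderedGeneTreeSet(tree=tree, orders=new_orders)


# ---------------------------------------------------------------------------
# histories and validation
# ---------------------------------------------------------------------------


@dataclass
class History:
    """A forward sequence of events from an initial state.

    ``initial`` is normally a single ancestral gene.  Intermediate states are
    recomputed on demand by :meth:`replay`; speciation events must name their
    daughter genomes so a history is self-contained.
    """

    initial: OrderedGeneTreeSet
    events: list[Event]
    species_tree: SpeciesTree | None = None

    def replay(
        self,
        label_factory: LabelFactory = default_label_factory,
        allow_empty_genome: bool = False,
    ) -> Iterator[OrderedGeneTreeSet]:
        """Yield every state of the history, starting with ``initial``."""
        state = self.initial
        yield state
        for ev in self.events:
            state = apply_event(state, ev, label_factory, allow_empty_genome)
            yield state

    def final_state(self, **kw) -> OrderedGeneTreeSet:
        state = self.initial
        for state in self.replay(**kw):
            pass
        return state

    def induced_species_sequence(self) -> list[tuple[str, tuple[str, str]]]:
        """The speciations of the history as (parent genome, daughters)."""
        return [(e.genome, e.children) for e in self.events if e.etype == "spec"]


@dataclass(frozen=True)
class ValidationReport:
    ok: bool
    message: str = ""
    step: int | None = None  # index of the first diverging event, if known

    def __bool__(self) -> bool:
        return self.ok


def validate_history(
    history: History,
    observed_orders: Mapping[str, Order],
    gene_tree: GeneTree | None = None,
    allow_empty_genome: bool = False,
) -> ValidationReport:
    """Replay a history forward and compare against the observation.

    The replay's own leaf naming generally differs from the observed gene ids,
    so the comparison is made under the position bijection: orders must match
    genome by genome in length and signs, and the replayed gene tree must be
    isomorphic to ``gene_tree`` once replayed leaves are renamed to the
    observed gene occupying the same position.
    """
    try:
        final = history.final_state(allow_empty_genome=allow_empty_genome)
    except ModelError as exc:
        return ValidationReport(False, f"replay failed: {exc}")

    if set(final.orders) != set(observed_orders):
        return ValidationReport(
            False,
            f"genome sets differ: replay {sorted(final.orders)} vs "
            f"observed {sorted(observed_orders)}",
            step=len(history.events),
        )
    bijection: dict[str, str] = {}
    for genome, obs in observed_orders.items():
        got = final.orders[genome]
        if len(got) != len(obs):
            return ValidationReport(
                False, f"genome {genome!r}: length {len(got)} != {len(obs)}",
                step=len(history.events),
            )
        for (g_rep, s_rep), (g_obs, s_obs) in zip(got, obs):
            if s_rep != s_obs:
                return ValidationReport(
                    False, f"genome {genome!r}: sign mismatch at gene {g_obs!r}",
                    step=len(history.events),
                )
            bijection[g_rep] = g_obs
    if len(set(bijection.values())) != len(bijection):
        return ValidationReport(False, "replay/observation gene map is not a bijection")

    if gene_tree is not None:
        if topo_signature(final.tree, bijection) != topo_signature(gene_tree.root):
            return ValidationReport(
                False, "replayed gene tree is not isomorphic to the observed tree",
                step=len(history.events),
            )
        genome_of = final.genome_of()
        for g_rep, g_obs in bijection.items():
            if gene_tree.leaf_genomes[g_obs] != genome_of[g_rep]:
                return ValidationReport(
                    False, f"gene {g_obs!r} assigned to the wrong genome"
                )
    return ValidationReport(True, "history reproduces the observation")
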