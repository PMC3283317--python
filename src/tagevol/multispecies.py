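"""Multi-species inference: gluing per-branch backward searches over the
species tree.

The species tree is traversed bottom-up.  At each internal vertex ``A`` with
children ``A_l`` and ``A_r``:

1. the backward search runs on each element of the child solution sets up
   the corresponding branch, stopping as soon as the attained order holds
   ``|PG(A_s)|`` genes; only the orders attained at the minimum cost ``MIN``
   over all elements are kept (per-branch truncation), and the partial
   solution graph is pruned to minimum-cost paths;
2. the genes lost on each branch are reinserted into the surviving orders in
   every possible position and sign (the combinatorial closure -- guarded by
   a configurable cap, as the closure is exponential in the number of lost
   copies);
3. the union of the two extended sets forms the solution set ``E(A)``;
4. each element of ``E(A)`` is connected by a *speciation edge* to its
   originating order on its own side, and to the element(s) of the other
   side's pre-speciation layer at minimum Inversions+Deletions (ID)
   distance.

Above the species root the search continues down to a single ancestral gene.
A concrete history is finally extracted by choosing, over the resulting
solution graph, a minimum-cost system of root-to-leaf paths, converting the
ID labels of the chosen speciation edges into explicit inversion/deletion
events, and replaying everything forward for validation.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter, deque
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from tagevol.model import (
    CostModel,
    DEFAULT_COSTS,
    Event,
    GeneTree,
    History,
    ModelError,
    Order,
    SpeciesTree,
    ValidationReport,
    event_cost,
    single_gene_state,
    validate_history,
)
from tagevol.reconcile import Reconciliation, lca_reconcile
from tagevol.search import SearchParams, SearchResult, backward_search

__all__ = [
    "ExtensionOverflow",
    "InferenceError",
    "IDDistance",
    "MultiResult",
    "branch_event_report",
    "duplication_size_counts",
    "extend_with_losses",
    "id_distance",
    "infer_history",
]


class ExtensionOverflow(ModelError):
    """Loss reinsertion would enumerate more orders than the configured cap."""


class InferenceError(ModelError):
    """A branch search produced no ancestral order (e.g. with the required
    event types disabled)."""


# ---------------------------------------------------------------------------
# loss reinsertion
# ---------------------------------------------------------------------------


def _closure_size(n: int, k: int) -> int:
    """Number of distinct orders after inserting ``k`` signed genes anywhere
    into a length-``n`` order: (n+k)!/n! * 2**k."""
    c = 2**k
    for i in range(n + 1, n + k + 1):
        c *= i
    return c


def extend_with_losses(
    order: Order, lost_genes: Sequence[str], cap: int = 10_000
) -> set[Order]:
    """All orders obtained by inserting every lost gene at every position
    with either sign (full combinatorial closure over the insertion set)."""
    lost = sorted(lost_genes)
    present = {g for g, _ in order}
    if present & set(lost):
        raise ModelError("lost genes must be disjoint from the order")
    total = _closure_size(len(order), len(lost))
    if total > cap:
        raise ExtensionOverflow(
            f"reinserting {len(lost)} lost genes into a {len(order)}-gene order "
            f"yields {total} candidates (cap {cap})"
        )
    out = {order}
    for g in lost:
        nxt: set[Order] = set()
        for o in out:
            for pos in range(len(o) + 1):
                for sign in (1, -1):
                    nxt.add(o[:pos] + ((g, sign),) + o[pos:])
        out = nxt
    return out


# ---------------------------------------------------------------------------
# ID distance (inversions + deletions)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IDDistance:
    """Minimum number of inversions plus deletions transforming x into y.

    ``events`` realises the distance (spans are positional, applied in
    sequence).  ``exact`` is False when the value comes from the documented
    upper-bound heuristic (delete maximal runs of absent genes, then sort the
    remainder by inversions) instead of the breadth-first state search.
    """

    count: float
    events: tuple[Event, ...]
    exact: bool = True


def _apply_ops(order: Order, events: Iterable[Event]) -> Order:
    cur = order
    for ev in events:
        p, q = ev.span
        if ev.etype == "inv":
            cur = cur[: p - 1] + tuple((g, -s) for g, s in reversed(cur[p - 1 : q])) + cur[q:]
        elif ev.etype == "del":
            cur = cur[: p - 1] + cur[q:]
        else:  # pragma: no cover
            raise ModelError("ID paths only contain inversions and deletions")
    return cur


def _greedy_inversion_sort(x: Order, y: Order) -> tuple[Event, ...]:
    """Upper-bound reversal sort of x into y (same gene content): place each
    target gene left to right, at most two reversals per position."""
    cur = list(x)
    events = []

    def rev(p: int, q: int) -> None:  # 0-based inclusive
        cur[p : q + 1] = [(g, -s) for g, s in reversed(cur[p : q + 1])]
        events.append(Event("inv", "*", (p + 1, q + 1)))

    for i, (g, s) in enumerate(y):
        j = next(k for k in range(i, len(cur)) if cur[k][0] == g)
        if j != i:
            rev(i, j)
        if cur[i][1] != s:
            rev(i, i)
    return tuple(events)


def _inversion_bfs(
    x: Order, y: Order, ub: tuple[Event, ...], node_cap: int
) -> tuple[tuple[Event, ...], bool]:
    """Exact reversal distance by BFS, bounded above by the greedy solution.
    Returns (events, exact)."""
    if x == y:
        return (), True
    best = len(ub)
    frontier = {x: ()}
    seen = {x}
    n = len(x)
    for depth in range(1, best):
        nxt: dict[Order, tuple] = {}
        for state, path in frontier.items():
            for p in range(n):
                for q in range(p, n):
                    ns = (
                        state[:p]
                        + tuple((g, -s) for g, s in reversed(state[p : q + 1]))
                        + state[q + 1 :]
                    )
                    if ns in seen:
                        continue
                    seen.add(ns)
                    npath = path + (Event("inv", "*", (p + 1, q + 1)),)
                    if ns == y:
                        return npath, True
                    nxt[ns] = npath
            if len(seen) > node_cap:
                return ub, False
        frontier = nxt
    return ub, True  # the greedy bound is optimal


def _delete_then_sort(
    x: Order, y: Order, ops: frozenset, node_cap: int, exact_remainder: bool = True
) -> IDDistance:
    """Delete maximal runs of absent genes, then sort the remainder by
    inversions (exact for short remainders, greedy beyond)."""
    needed = {g for g, _ in y}
    cur = list(x)
    events: list[Event] = []
    # delete maximal runs of absent genes, right to left
    i = len(cur) - 1
    while i >= 0:
        if cur[i][0] not in needed:
            j = i
            while j >= 0 and cur[j][0] not in needed:
                j -= 1
            events.append(Event("del", "*", (j + 2, i + 1)))
            del cur[j + 1 : i + 1]
            i = j
        else:
            i -= 1
    if events and "del" not in ops:
        return IDDistance(math.inf, (), exact=False)
    remainder = tuple(cur)
    if remainder == y:
        return IDDistance(len(events), tuple(events), exact=True)
    if "inv" not in ops:
        return IDDistance(math.inf, (), exact=False)
    greedy = _greedy_inversion_sort(remainder, y)
    if exact_remainder and len(remainder) <= 8:
        inv_events, _ = _inversion_bfs(remainder, y, greedy, node_cap)
    else:
        inv_events = greedy
    return IDDistance(len(events) + len(inv_events), tuple(events) + inv_events, True)


def _heuristic_id(x: Order, y: Order, ops: frozenset, node_cap: int) -> IDDistance:
    """Constructive upper bound on the ID distance.

    Base strategy: delete maximal runs of absent genes, then sort the
    remainder by inversions.  A one-inversion lookahead additionally tries
    every single leading inversion of ``x`` -- an inversion can merge two
    runs of doomed genes (saving a deletion) while simultaneously placing a
    surviving gene, which the delete-first order cannot express.  Every
    candidate is an explicit event list, so the bound is always realisable.
    """
    base = _delete_then_sort(x, y, ops, node_cap)
    # a cheaper solution needs >= 1 deletion and >= 1 more op after the
    # leading inversion, so nothing below a base cost of 3 can be improved
    if "inv" not in ops or not math.isfinite(base.count) or base.count <= 2:
        return base
    n = len(x)

    def inv(o: Order, p: int, q: int) -> Order:
        return o[:p] + tuple((g, -s) for g, s in reversed(o[p : q + 1])) + o[q + 1 :]

    best_prefix: tuple | None = None
    best_count = base.count
    for p in range(n):
        for q in range(p, n):
            x2 = inv(x, p, q)
            cand = _delete_then_sort(x2, y, ops, node_cap, exact_remainder=False)
            if 1 + cand.count < best_count:
                best_count = 1 + cand.count
                best_prefix = ((p, q),)
    # a second leading inversion only pays off for loose bounds on short
    # orders; beyond that the quartic scan is not worth its cost
    if best_count >= 4 and n <= 10:
        for p1 in range(n):
            for q1 in range(p1, n):
                x2 = inv(x, p1, q1)
                for p2 in range(n):
                    for q2 in range(p2, n):
                        cand = _delete_then_sort(
                            inv(x2, p2, q2), y, ops, node_cap, exact_remainder=False
                        )
                        if 2 + cand.count < best_count:
                            best_count = 2 + cand.count
                            best_prefix = ((p1, q1), (p2, q2))
    if best_prefix is None:
        return base
    cur = x
    prefix_events = []
    for p, q in best_prefix:
        cur = inv(cur, p, q)
        prefix_events.append(Event("inv", "*", (p + 1, q + 1)))
    tail = _delete_then_sort(cur, y, ops, node_cap)
    return IDDistance(
        len(prefix_events) + tail.count,
        tuple(prefix_events) + tail.events,
        True,
    )


def id_distance(
    x: Order,
    y: Order,
    exact_bound: int = 8,
    ops: Iterable[str] = ("inv", "del"),
    node_cap: int = 500_000,
) -> IDDistance:
    """Minimum Inversions+Deletions distance transforming ``x`` into ``y``.

    Exact by breadth-first search over the inversion/deletion state space for
    ``len(x) <= exact_bound``; beyond that bound the documented upper-bound
    heuristic is used and ``exact`` is False.  ``ops`` restricts the allowed
    operations (e.g. deletions only, for clusters where inversions are
    disallowed); an unreachable target yields an infinite count.
    """
    ops = frozenset(ops)
    ids_x = [g for g, _ in x]
    ids_y = [g for g, _ in y]
    if len(set(ids_x)) != len(ids_x) or len(set(ids_y)) != len(ids_y):
        raise ModelError("ID distance requires duplicate-free orders")
    if not set(ids_y) <= set(ids_x):
        raise ModelError("target order contains genes absent from the source")
    if x == y:
        return IDDistance(0, ())
    heur = _heuristic_id(x, y, ops, node_cap)
    if len(x) > exact_bound:
        return replace(heur, exact=False)
    if not math.isfinite(heur.count):
        # restricted op set: BFS over the allowed ops alone, unbounded above
        ub = len(x) * (len(x) + 3)  # loose; unreachable targets exhaust first
    else:
        ub = heur.count
    needed = {g for g, _ in y}
    frontier: dict[Order, tuple] = {x: ()}
    seen = {x}
    depth = 0
    while frontier and depth + 1 < ub:
        depth += 1
        nxt: dict[Order, tuple] = {}
        for state, path in frontier.items():
            n = len(state)
            succs: list[tuple[Order, Event]] = []
            if "inv" in ops:
                for p in range(n):
                    for q in range(p, n):
                        ns = (
                            state[:p]
                            + tuple((g, -s) for g, s in reversed(state[p : q + 1]))
                            + state[q + 1 :]
                        )
                        succs.append((ns, Event("inv", "*", (p + 1, q + 1))))
            if "del" in ops:
                for p in range(n):
                    if state[p][0] in needed:
                        continue
                    for q in range(p, n):
                        if state[q][0] in needed:
                            break
                        succs.append(
                            (state[:p] + state[q + 1 :], Event("del", "*", (p + 1, q + 1)))
                        )
            for ns, ev in succs:
                if ns in seen:
                    continue
                seen.add(ns)
                npath = path + (ev,)
                if ns == y:
                    return IDDistance(depth, npath, exact=True)
                if len(ns) > len(y):  # shorter than target: dead end
                    nxt[ns] = npath
                elif len(ns) == len(y) and "inv" in ops:
                    nxt[ns] = npath
            if len(seen) > node_cap:
                return replace(heur, exact=False)
        frontier = nxt
    if math.isfinite(heur.count):
        return heur  # the heuristic bound is optimal
    return IDDistance(math.inf, (), exact=True)


# ---------------------------------------------------------------------------
# the multi-species algorithm
# ---------------------------------------------------------------------------


@dataclass
class MultiResult:
    """Outcome of a multi-species inference.

    ``solution_sets`` maps every species vertex to its candidate ancestral
    orders E(A) (observed orders at the leaves).  ``branch_costs`` holds the
    per-branch minimum search cost, keyed by the branch's lower vertex (the
    species root keys the pre-root lineage down to one gene).  The reported
    ``total_cost`` adds the cost-model conversion of the chosen speciation
    edges' ID events to the branch costs; ``id_label_total`` is the plain
    event-count sum of those labels as the edges are printed.
    """

    reconciliation: Reconciliation
    solution_sets: dict[str, list[Order]]
    branch_results: dict[str, SearchResult]
    branch_costs: dict[str, float]
    pg_layers: dict[str, dict[Order, list]]
    ext_maps: dict[str, dict[Order, frozenset]]
    root_candidate: Order
    chosen_edges: dict[tuple[str, str], tuple]
    branch_cost: float
    id_event_cost: float
    id_label_total: int
    history: History
    validation: ValidationReport

    @property
    def total_cost(self) -> float:
        return self.branch_cost + self.id_event_cost

    def solution_graph(self):
        """Global solution graph: per-branch minimum-cost path DAGs joined by
        ID-labelled speciation edges (networkx DiGraph)."""
        import networkx as nx

        g = nx.DiGraph()
        for a, res in self.branch_results.items():
            for k, bps in res.backpointers.items():
                g.add_node((a, k[0]))
                for succ, ev in bps:
                    g.add_edge((a, k[0]), (a, succ[0]), event=ev, kind="event")
        for (a, s), (x, y, idr, *_rest) in self.chosen_edges.items():
            g.add_edge((a, x), (s, y), id_label=idr.count, kind="speciation")
        return g


def infer_history(
    gene_tree: GeneTree,
    leaf_orders: Mapping[str, Order],
    species_tree: SpeciesTree,
    costs: CostModel = DEFAULT_COSTS,
    params: SearchParams = SearchParams(),
    reconciliation: Reconciliation | None = None,
    extension_cap: int = 10_000,
    id_exact_bound: int = 8,
    id_plain_labels: bool = False,
) -> MultiResult:
    """Infer a most-parsimonious multi-species history.

    ``leaf_orders`` maps each extant genome to its observed signed order;
    genomes must match the species-tree leaves and gene ids the gene-tree
    leaves.  A precomputed ``reconciliation`` may be supplied; otherwise the
    LCA reconciliation is used.
    """
    st = species_tree
    if set(leaf_orders) != set(st.leaves):
        raise ModelError("leaf orders must cover exactly the species-tree leaves")
    tree_genes = set(gene_tree.leaves)
    order_genes = {g for o in leaf_orders.values() for g, _ in o}
    if tree_genes != order_genes:
        raise ModelError("gene-tree leaves and order contents differ")
    rec = reconciliation if reconciliation is not None else lca_reconcile(gene_tree, st)

    id_ops = frozenset(t for t in ("inv", "del") if t in costs.enabled)

    E: dict[str, list[Order]] = {}
    branch_results: dict[str, SearchResult] = {}
    branch_costs: dict[str, float] = {}
    pg_layers: dict[str, dict[Order, list]] = {}
    ext_maps: dict[str, dict[Order, frozenset]] = {}

    for leaf in st.leaves:
        E[leaf] = [tuple(leaf_orders[leaf])]

    def run_branch(s: str, parent_vertex: str) -> None:
        """Search the branch (parent, s), truncate, reinsert losses."""
        target = len(rec.pre_speciation_sets[s])
        forest = rec.branch_forests[s]
        root_map = rec.branch_root_maps[s]
        res = backward_search(E[s], forest, target, costs, params, genome="*")
        if res.min_cost is None or not res.solutions:
            raise InferenceError(
                f"no ancestral order found on the branch entering {s!r} "
                "(check the enabled event types)"
            )
        branch_results[s] = res
        branch_costs[s] = res.min_cost
        layer: dict[Order, list] = {}
        for sol in res.solutions:
            order, _ = sol
            relabeled = tuple((root_map[g], sign) for g, sign in order)
            layer.setdefault(relabeled, []).append(sol)
        pg_layers[s] = layer
        lost = rec.losses[(parent_vertex, s)]
        ext: dict[Order, set] = {}
        for y in layer:
            for e in extend_with_losses(y, lost, cap=extension_cap):
                ext.setdefault(e, set()).add(y)
        ext_maps[s] = {e: frozenset(v) for e, v in ext.items()}

    for a in st.postorder():
        if st.is_leaf(a):
            continue
        for s in st.children[a]:
            run_branch(s, a)
        merged = sorted(set(ext_maps[st.children[a][0]]) | set(ext_maps[st.children[a][1]]))
        E[a] = merged

    # pre-root lineage: continue down to a single ancestral gene
    root = st.root
    res_root = backward_search(
        E[root], rec.branch_forests[root], 1, costs, params, genome="*"
    )
    if res_root.min_cost is None or not res_root.solutions:
        raise InferenceError(
            "no single-gene ancestor found above the species root "
            "(check the enabled event types)"
        )
    branch_results[root] = res_root
    branch_costs[root] = res_root.min_cost

    # --- choose a minimum-cost path system over the solution graph ---------
    def id_edge_cost(idr: IDDistance) -> float:
        if id_plain_labels:
            return float(idr.count)
        return sum(event_cost(ev, costs) for ev in idr.events)

    memo: dict[tuple[str, Order], tuple] = {}

    def cost_down(a: str, x: Order):
        """Minimum downstream ID-edge cost for candidate ``x`` at internal
        vertex ``a``; returns (cost, {child: choice})."""
        key = (a, x)
        if key in memo:
            return memo[key]
        total = 0.0
        choice: dict[str, tuple] = {}
        for s in st.children[a]:
            layer = pg_layers[s]
            if x in ext_maps[s]:
                ys = sorted(ext_maps[s][x])  # edges to the originating orders
            else:
                dists = [(id_distance(x, y, id_exact_bound, id_ops).count, y) for y in sorted(layer)]
                dmin = min(d for d, _ in dists)
                if not math.isfinite(dmin):
                    raise InferenceError(
                        f"no inversion/deletion path from {x} into the branch "
                        f"entering {s!r} under the enabled event types"
                    )
                ys = [y for d, y in dists if d == dmin]
            best = None
            for y in ys:
                idr = id_distance(x, y, id_exact_bound, id_ops)
                if not math.isfinite(idr.count):
                    continue
                e_cost = id_edge_cost(idr)
                res = branch_results[s]
                for raw in layer[y]:
                    for zi in sorted(res.origins(raw)):
                        z = res.starts[zi][0]
                        if st.is_leaf(s):
                            cont, _ = 0.0, None
                        else:
                            cont, _ = cost_down(s, z)
                        cand = (e_cost + cont, y, raw, zi, idr)
                        if best is None or cand[:2] < best[:2]:
                            best = cand
            if best is None:
                raise InferenceError(
                    f"no feasible speciation edge towards {s!r} from {x}"
                )
            total += best[0]
            choice[s] = best
        memo[key] = (total, choice)
        return memo[key]

    allowed_root_idx = sorted(
        set().union(*(res_root.origins(sol) for sol in res_root.solutions))
    )
    best_root = None
    for idx in allowed_root_idx:
        x = res_root.starts[idx][0]
        c, _ = cost_down(root, x)
        cand = (c, x, idx)
        if best_root is None or cand < best_root:
            best_root = cand
    id_cost_total, x_root, root_idx = best_root

    # --- traceback into an explicit history --------------------------------
    events: list[Event] = []
    chosen_edges: dict[tuple[str, str], tuple] = {}

    sol_star = next(
        s for s in res_root.solutions if root_idx in res_root.origins(s)
    )
    pre_events, _ = res_root.extract_path(sol_star, start_index=root_idx)
    events.extend(replace(ev, genome=root, branch=root) for ev in pre_events)

    id_label_total = 0

    def descend(a: str, x: Order) -> None:
        nonlocal id_label_total
        left, right = st.children[a]
        events.append(
            Event("spec", genome=a, children=(left, right), branch=a)
        )
        for s in (left, right):
            _, choice = cost_down(a, x)
            _cost, y, raw, zi, idr = choice[s]
            chosen_edges[(a, s)] = (x, y, idr, raw, zi)
            id_label_total += int(idr.count)
            events.extend(replace(ev, genome=s, branch=s) for ev in idr.events)
            res = branch_results[s]
            branch_events, _ = res.extract_path(raw, start_index=zi)
            events.extend(replace(ev, genome=s, branch=s) for ev in branch_events)
            if not st.is_leaf(s):
                descend(s, res.starts[zi][0])

    anc_label, anc_sign = sol_star[0][0]
    initial = single_gene_state(gene_id=anc_label, genome=root, sign=anc_sign)
    descend(root, x_root)

    history = History(initial=initial, events=events, species_tree=st)
    validation = validate_history(history, leaf_orders, gene_tree)

    branch_cost = sum(branch_costs.values())
    # id_event_cost independent of the plain-label flag: always the converted sum
    id_event_cost = sum(
        sum(event_cost(ev, costs) for ev in idr.events)
        for (_x, _y, idr, *_r) in chosen_edges.values()
    )

    return MultiResult(
        reconciliation=rec,
        solution_sets={a: list(E[a]) for a in E},
        branch_results=branch_results,
        branch_costs=branch_costs,
        pg_layers=pg_layers,
        ext_maps=ext_maps,
        root_candidate=x_root,
        chosen_edges=chosen_edges,
        branch_cost=branch_cost,
        id_event_cost=id_event_cost,
        id_label_total=id_label_total,
        history=history,
        validation=validation,
    )


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


def branch_event_report(history: History):
    """Per-branch event counts from a traced-back history.

    A compound duplication-with-deletion counts as one duplication and one
    deletion; a deletion of ``m`` genes counts as one deletion and ``m`` gene
    losses.  Speciations are not counted.
    """
    import pandas as pd

    rows: dict[str, Counter] = {}
    for ev in history.events:
        if ev.etype == "spec":
            continue
        branch = ev.branch if ev.branch is not None else ev.genome
        c = rows.setdefault(branch, Counter())
        if ev.etype in ("dup", "idup"):
            c[ev.etype] += 1
            if ev.deleted_subspan is not None:
                c["del"] += 1
                c["gene_losses"] += ev.del_size
        elif ev.etype == "del":
            c["del"] += 1
            c["gene_losses"] += ev.size
        elif ev.etype == "inv":
            c["inv"] += 1
    out = []
    for branch in sorted(rows):
        c = rows[branch]
        out.append(
            {
                "branch": branch,
                "dup": c.get("dup", 0),
                "idup": c.get("idup", 0),
                "inv": c.get("inv", 0),
                "del": c.get("del", 0),
                "gene_losses": c.get("gene_losses", 0),
            }
        )
    return pd.DataFrame(
        out, columns=["branch", "dup", "idup", "inv", "del", "gene_losses"]
    )


def duplication_size_counts(history: History) -> Counter:
    """Histogram of duplication sizes (direct + inverted) in a history."""
    sizes: Counter = Counter()
    for ev in history.events:
        if ev.etype in ("dup", "idup"):
            sizes[ev.size] += 1
    return sizes
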