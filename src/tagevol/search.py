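"""Single-branch backward search over the history graph.

The history graph has ordered gene trees as vertices and evolutionary events
as edges.  Inference explores it *backwards* from an observed state: for each
state we enumerate the predecessor states that could have produced it by one
event (duplication, inverted duplication, inversion, or a duplication
immediately followed by a deletion inside the fresh copy region).  Bare
deletions are deliberately absent from the graph -- allowing them would make
the search space infinite -- so deletions exist only in combination with
duplications; deletions of genes surviving across speciations are handled
separately by the multi-species layer.

A search *state* is ``(order, forest)``: the signed gene order plus a forest
of cherry trees.  For a single observed cluster the forest is the whole gene
tree; on an internal branch of the species tree it is the reconciled gene
tree restricted to that branch (one tree per ancestral gene surviving the
speciation).  Collapsing a cherry ``(l, r)`` replaces it by a leaf carrying
the parent's label, so gene naming along any backward path is deterministic.

The search itself is a greedy beam expansion that retains at most
``queue_capacity`` partial histories per depth round; it stops expanding a
state once its order holds exactly ``g`` genes, and returns the minimum cost
``MIN`` together with the set of ancestral orders attained at ``MIN`` and
the DAG of the minimum-cost backward paths it retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from tagevol.model import (
    CostModel,
    DEFAULT_COSTS,
    Event,
    ModelError,
    Node,
    Order,
    OrderedGeneTreeSet,
    cherries,
    collapse_cherries,
    internal,
    topo_signature,
)

Forest = frozenset  # frozenset of tree Nodes
State = tuple  # (Order, Forest)

__all__ = [
    "SearchParams",
    "SearchResult",
    "backward_search",
    "duplication_predecessors",
    "inverted_duplication_predecessors",
    "inversion_predecessors",
    "duplication_with_deletion_predecessors",
    "all_predecessors",
    "forest_cherries",
    "forest_to_state",
    "state_signature",
]


def forest_cherries(forest: Forest) -> dict[str, tuple[str, str]]:
    """Cherry map over a forest: leaf -> (sibling, parent label).

    Computed per tree so that adjacent roots of different trees never form a
    spurious cherry.
    """
    out: dict[str, tuple[str, str]] = {}
    for root in forest:
        out.update(cherries(root))
    return out


def _collapse(forest: Forest, parents: frozenset) -> Forest:
    return frozenset(collapse_cherries(r, parents) for r in forest)


# ---------------------------------------------------------------------------
# predecessor neighbourhoods
# ---------------------------------------------------------------------------


def duplication_predecessors(
    order: Order, forest: Forest, genome: str = "*", ch=None
) -> list[tuple[Order, Forest, Event]]:
    """Undo tandem duplications: every window ``(l_p..l_q, r_p..r_q)`` of
    ``2m`` contiguous genes where each ``(l_x, r_x)`` is an equal-signed
    cherry collapses to the ancestral segment ``(u_p..u_q)``."""
    n = len(order)
    if ch is None:
        ch = forest_cherries(forest)
    out = []
    for m in range(1, n // 2 + 1):
        for i in range(0, n - 2 * m + 1):
            seg = []
            ok = True
            for x in range(m):
                ga, sa = order[i + x]
                gb, sb = order[i + m + x]
                mate = ch.get(ga)
                if sa != sb or mate is None or mate[0] != gb:
                    ok = False
                    break
                seg.append((mate[1], sa))
            if ok:
                parents = frozenset(g for g, _ in seg)
                pred = order[:i] + tuple(seg) + order[i + 2 * m :]
                out.append(
                    (
                        pred,
                        _collapse(forest, parents),
                        Event("dup", genome, (i + 1, i + m)),
                    )
                )
    return out


def inverted_duplication_predecessors(
    order: Order, forest: Forest, genome: str = "*", ch=None
) -> list[tuple[Order, Forest, Event]]:
    """Undo inverted duplications, both placements of the reversed block:
    ``(-l_q..-l_p, r_p..r_q)`` (variant ``left``) and
    ``(l_p..l_q, -r_q..-r_p)`` (variant ``right``)."""
    n = len(order)
    if ch is None:
        ch = forest_cherries(forest)
    out = []
    for m in range(1, n // 2 + 1):
        for i in range(0, n - 2 * m + 1):
            # variant left: first block reversed & negated
            seg = []
            ok = True
            for x in range(m):
                gl, sl = order[i + (m - 1 - x)]
                gr, sr = order[i + m + x]
                mate = ch.get(gl)
                if sl != -sr or mate is None or mate[0] != gr:
                    ok = False
                    break
                seg.append((mate[1], sr))
            if ok:
                parents = frozenset(g for g, _ in seg)
                out.append(
                    (
                        order[:i] + tuple(seg) + order[i + 2 * m :],
                        _collapse(forest, parents),
                        Event("idup", genome, (i + 1, i + m), variant="left"),
                    )
                )
            # variant right: second block reversed & negated
            seg = []
            ok = True
            for x in range(m):
                gl, sl = order[i + x]
                gr, sr = order[i + 2 * m - 1 - x]
                mate = ch.get(gl)
                if sl != -sr or mate is None or mate[0] != gr:
                    ok = False
                    break
                seg.append((mate[1], sl))
            if ok:
                parents = frozenset(g for g, _ in seg)
                out.append(
                    (
                        order[:i] + tuple(seg) + order[i + 2 * m :],
                        _collapse(forest, parents),
                        Event("idup", genome, (i + 1, i + m), variant="right"),
                    )
                )
    return out


def inversion_predecessors(
    order: Order, forest: Forest, genome: str = "*"
) -> list[tuple[Order, Forest, Event]]:
    """Undo inversions: one predecessor per contiguous span (the inversion is
    an involution), ``n(n+1)/2`` predecessors in total."""
    n = len(order)
    out = []
    for p in range(n):
        for q in range(p, n):
            seg = tuple((g, -s) for g, s in reversed(order[p : q + 1]))
            out.append(
                (
                    order[:p] + seg + order[q + 1 :],
                    forest,
                    Event("inv", genome, (p + 1, q + 1)),
                )
            )
    return out


# (lmode, rmode, sign_rel, pred_from_l, lmul, rmul, etype, variant)
# lmode/rmode give the full-coordinate position of l_x / r_x in the 2m-gene
# copy region: mode 0 -> x / m+x, mode 1 -> m-1-x / 2m-1-x (reversed block).
_COMPOUND_KINDS = (
    (0, 0, 1, False, 1, 1, "dup", None),
    (1, 0, -1, False, -1, 1, "idup", "left"),
    (0, 1, -1, True, 1, -1, "idup", "right"),
)


def duplication_with_deletion_predecessors(
    order: Order,
    forest: Forest,
    genome: str = "*",
    include_inverted: bool = True,
    ch=None,
) -> list[tuple[Order, Forest, Event]]:
    """Undo compound duplication-then-deletion events.

    The forward compound duplicates ``m`` genes and immediately deletes one
    contiguous run of ``d`` copies (``1 <= d <= m-1``) from one of the two
    copy blocks.  Backwards, the observed window holds ``2m - d`` genes:
    positions where both copies survive must form sign-consistent cherries
    (these anchor the pattern) and positions where one copy was deleted keep
    the surviving copy, relabelled to the ancestral gene.  Restricting the
    deleted run to a single block keeps this neighbourhood quadratic; multiple
    deleted runs emerge as successive compound events.
    """
    n = len(order)
    if ch is None:
        ch = forest_cherries(forest)
    if not ch:
        return []
    kinds = _COMPOUND_KINDS if include_inverted else _COMPOUND_KINDS[:1]
    signs = [s for _, s in order]
    pos_of = {g: j for j, (g, _) in enumerate(order)}
    # mate_pos[j] = position of order[j]'s cherry sibling (or -1)
    mate_pos = [-1] * n
    parent_at = [""] * n
    for j, (g, _) in enumerate(order):
        mt = ch.get(g)
        if mt is not None and mt[0] in pos_of:
            mate_pos[j] = pos_of[mt[0]]
            parent_at[j] = mt[1]
    # prefix count of cherry-leaf positions, to skip windows without anchors
    pre = [0]
    for j in range(n):
        pre.append(pre[-1] + (1 if mate_pos[j] >= 0 else 0))
    out = []
    for m in range(2, n):
        for d in range(1, m):
            w = 2 * m - d
            if w > n:
                continue  # larger d gives a smaller window; keep going
            span_of_r0 = m - d + 1
            for i in range(0, n - w + 1):
                if pre[i + w] - pre[i] < 2:
                    continue  # no cherry pair can anchor this window
                for first_block in (True, False):
                    base = 0 if first_block else m
                    for r0 in range(0, span_of_r0):
                        a = base + r0  # deleted full positions a..a+d-1
                        b = a + d
                        for lmode, rmode, rel, from_l, lmul, rmul, et, var in kinds:
                            # ancestral positions x whose copy was deleted
                            if first_block:
                                da, db = (m - b, m - a) if lmode else (a, b)
                            else:
                                da, db = (2 * m - b, 2 * m - a) if rmode else (a - m, b - m)
                            # check the surviving pairs first (fail fast)
                            ok = True
                            for x in range(0, da):
                                fl = m - 1 - x if lmode else x
                                fr = 2 * m - 1 - x if rmode else m + x
                                p1 = i + (fl - d if fl >= b else fl)
                                p2 = i + (fr - d if fr >= b else fr)
                                if mate_pos[p1] != p2 or signs[p1] != rel * signs[p2]:
                                    ok = False
                                    break
                            if ok:
                                for x in range(db, m):
                                    fl = m - 1 - x if lmode else x
                                    fr = 2 * m - 1 - x if rmode else m + x
                                    p1 = i + (fl - d if fl >= b else fl)
                                    p2 = i + (fr - d if fr >= b else fr)
                                    if mate_pos[p1] != p2 or signs[p1] != rel * signs[p2]:
                                        ok = False
                                        break
                            if not ok:
                                continue
                            # build the collapsed ancestral segment
                            seg = []
                            parents = []
                            for x in range(m):
                                fl = m - 1 - x if lmode else x
                                fr = 2 * m - 1 - x if rmode else m + x
                                if da <= x < db:  # one copy deleted: survivor
                                    if a <= fl < b:  # the l copy is gone
                                        p2 = i + (fr - d if fr >= b else fr)
                                        seg.append((order[p2][0], rmul * signs[p2]))
                                    else:
                                        p1 = i + (fl - d if fl >= b else fl)
                                        seg.append((order[p1][0], lmul * signs[p1]))
                                else:
                                    p1 = i + (fl - d if fl >= b else fl)
                                    seg.append(
                                        (parent_at[p1], signs[p1] if from_l else rel * signs[p1])
                                    )
                                    parents.append(parent_at[p1])
                            p = i + 1
                            ev = Event(
                                et,
                                genome,
                                (p, p + m - 1),
                                variant=var,
                                deleted_subspan=(p + a, p + a + d - 1),
                            )
                            out.append(
                                (
                                    order[:i] + tuple(seg) + order[i + w :],
                                    _collapse(forest, frozenset(parents)),
                                    ev,
                                )
                            )
    return out


def all_predecessors(
    order: Order,
    forest: Forest,
    costs: CostModel = DEFAULT_COSTS,
    genome: str = "*",
) -> list[tuple[Order, Forest, Event, float]]:
    """Concatenated neighbourhood over all enabled operators, with costs.
    Disabled event types are skipped outright."""
    from tagevol.model import event_cost

    ch = forest_cherries(forest)
    cand: list[tuple[Order, Forest, Event]] = []
    if "dup" in costs.enabled:
        cand += duplication_predecessors(order, forest, genome, ch=ch)
    if "idup" in costs.enabled:
        cand += inverted_duplication_predecessors(order, forest, genome, ch=ch)
    if "inv" in costs.enabled:
        cand += inversion_predecessors(order, forest, genome)
    if "del" in costs.enabled and ("dup" in costs.enabled or "idup" in costs.enabled):
        cand += duplication_with_deletion_predecessors(
            order, forest, genome, include_inverted="idup" in costs.enabled, ch=ch
        )
    return [(o, f, e, event_cost(e, costs)) for o, f, e in cand]


# ---------------------------------------------------------------------------
# state helpers
# ---------------------------------------------------------------------------


def forest_to_state(
    order: Order, forest: Forest, genome: str = "*"
) -> OrderedGeneTreeSet:
    """Wrap a forest state into a replayable single-genome state by joining
    the trees under deterministic virtual ancestors (left comb over sorted
    roots).  Only used to replay/validate; the search never calls this."""
    roots = sorted(forest, key=lambda r: min(order_index(order, r)))
    node = roots[0]
    for k, r in enumerate(roots[1:]):
        node = internal(f"__virt{k}__", node, r)
    return OrderedGeneTreeSet(tree=node, orders={genome: order})


def order_index(order: Order, root: Node) -> list[int]:
    pos = {g: k for k, (g, _) in enumerate(order)}
    from tagevol.model import iter_leaves

    return sorted(pos[g] for g in iter_leaves(root))


def state_signature(order: Order, forest: Forest):
    """Label-free canonical identity of a state: gene signs by position plus
    the forest topology with leaves renamed to their order positions."""
    pos = {g: k for k, (g, _) in enumerate(order)}
    return (
        tuple(s for _, s in order),
        frozenset(topo_signature(r, pos) for r in forest),
    )


# ---------------------------------------------------------------------------
# best-first search
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SearchParams:
    """Knobs of the greedy backward search.

    ``queue_capacity`` bounds the number of retained partial histories (the
    search degrades gracefully to a heuristic when the frontier overflows);
    ``depth`` is the number of expansions between capacity enforcements
    (1 = pure best-first); ``max_solutions`` caps the solution set.
    """

    queue_capacity: int = 300
    depth: int = 1
    max_solutions: int = 256

    def __post_init__(self) -> None:
        if self.queue_capacity < 1 or self.depth < 1 or self.max_solutions < 1:
            raise ModelError("search parameters must be >= 1")


@dataclass
class SearchResult:
    """Outcome of one backward search.

    ``solutions`` holds the states (orders of exactly ``target`` genes, each
    tree of the forest collapsed to a single vertex) attained at the minimum
    cost ``min_cost``; ``backpointers`` is the DAG of minimum-cost backward
    paths (state -> [(successor state, undone event)]), rooted at the starts.
    """

    min_cost: float | None
    solutions: list[State]
    backpointers: dict
    dist: dict
    starts: list[State]
    target: int
    overflowed: bool = False
    solutions_capped: bool = False

    _origins_cache: dict | None = field(default=None, repr=False)

    def origins(self, key: State) -> frozenset:
        """Indices of the start states from which ``key`` is reachable along
        minimum-cost paths."""
        if self._origins_cache is None:
            self._origins_cache = {}
        cache = self._origins_cache
        start_idx = {s: i for i, s in enumerate(self.starts)}

        def rec(k):
            if k in cache:
                return cache[k]
            if not self.backpointers.get(k):
                res = frozenset({start_idx[k]})
            else:
                res = frozenset().union(
                    *(rec(succ) for succ, _ in self.backpointers[k])
                )
            cache[k] = res
            return res

        return rec(key)

    def extract_path(self, solution: State, start_index: int | None = None):
        """One minimum-cost path from ``solution`` down to a start state.

        Returns ``(events, start_index)`` where applying the events in order
        (forward replay) transforms the solution into the start state.
        """
        events: list[Event] = []
        cur = solution
        while self.backpointers.get(cur):
            chosen = None
            for succ, ev in self.backpointers[cur]:
                if start_index is None or start_index in self.origins(succ):
                    chosen = (succ, ev)
                    break
            if chosen is None:  # pragma: no cover - origins guarantee a path
                raise ModelError("no backward path to the requested start")
            events.append(chosen[1])
            cur = chosen[0]
        idx = self.starts.index(cur)
        return events, idx

    def solution_graph(self):
        """The minimum-cost path DAG as a networkx DiGraph (edges oriented
        from ancestral states towards the observed starts)."""
        import networkx as nx

        g = nx.DiGraph()
        for k, bps in self.backpointers.items():
            g.add_node(k)
            for succ, ev in bps:
                g.add_edge(k, succ, event=ev)
        return g


def _node_sort_repr(node: Node):
    """Deterministic, totally ordered representation of a tree node (frozenset
    iteration order is not stable across processes)."""
    if isinstance(node, str):
        return ("L", node)
    return ("N", node[1], tuple(sorted(_node_sort_repr(k) for k in node[2])))


def _state_sort_key(key: State):
    order, forest = key
    return (order, tuple(sorted(_node_sort_repr(r) for r in forest)))


def backward_search(
    starts: list[Order] | Order,
    forest: Forest,
    target: int,
    costs: CostModel = DEFAULT_COSTS,
    params: SearchParams = SearchParams(),
    genome: str = "*",
) -> SearchResult:
    """Greedy backward search from one or several observed orders (all
    sharing the same forest) to ancestral orders of exactly ``target`` genes.

    The frontier of partial histories is expanded one graph depth per round;
    every ``params.depth`` rounds it is pruned back to the
    ``params.queue_capacity`` most promising (cheapest) states, which bounds
    both time and memory and makes the search a heuristic on large inputs
    (``overflowed`` reports whether pruning ever triggered).  A state stops
    being expanded as soon as its order holds ``target`` genes; rounds
    continue until no retained partial history is cheaper than the best
    solution, so all minimum-cost ancestors reachable through the retained
    frontier are reported (up to ``params.max_solutions``).
    """
    if isinstance(starts, tuple) and starts and isinstance(starts[0], tuple):
        start_orders = [starts]
    else:
        start_orders = list(starts)
    if not start_orders:
        raise ModelError("at least one start order is required")
    n_roots = len(forest)
    for o in start_orders:
        if not (1 <= target <= len(o)):
            raise ModelError(f"target {target} out of range for order of {len(o)}")
    if target < n_roots:
        raise ModelError(
            f"target {target} below the number of forest trees ({n_roots}); "
            "each tree collapses to at least one gene"
        )

    dist: dict[State, float] = {}
    bp: dict[State, list] = {}
    expanded_at: dict[State, float] = {}
    sols: dict[State, float] = {}
    skey_cache: dict[State, tuple] = {}

    def skey(k: State):
        r = skey_cache.get(k)
        if r is None:
            r = _state_sort_key(k)
            skey_cache[k] = r
        return r

    frontier: list[State] = []
    for o in start_orders:
        key = (o, forest)
        if key in dist:
            continue
        dist[key] = 0.0
        bp[key] = []
        frontier.append(key)

    min_sol = math.inf
    overflowed = False
    capped = False
    rounds_since_prune = 0

    while frontier:
        # move completed states to the solution pool, drop hopeless ones
        live: list[State] = []
        for k in frontier:
            c = dist[k]
            if len(k[0]) == target:
                if c <= min_sol:
                    if len(sols) >= params.max_solutions and k not in sols:
                        capped = True
                    else:
                        sols[k] = c
                        min_sol = min(min_sol, c)
            elif c < min_sol:
                live.append(k)
        frontier = live
        # capacity enforcement: keep the cheapest partial histories
        rounds_since_prune += 1
        if rounds_since_prune >= params.depth and len(frontier) > params.queue_capacity:
            frontier.sort(key=lambda k: (dist[k], skey(k)))
            dropped = frontier[params.queue_capacity :]
            frontier = frontier[: params.queue_capacity]
            overflowed = True
            for k in dropped:  # never expanded: safe to forget entirely
                if k not in expanded_at:
                    dist.pop(k, None)
                    bp.pop(k, None)
                    skey_cache.pop(k, None)
            rounds_since_prune = 0
        if not frontier:
            break
        frontier.sort(key=lambda k: (dist[k], skey(k)))
        nxt: dict[State, None] = {}
        for k in frontier:
            c0 = dist[k]
            if c0 >= min_sol:
                continue  # positive event costs: cannot improve on MIN
            if expanded_at.get(k, math.inf) <= c0:
                continue  # already expanded at this (or a lower) cost
            expanded_at[k] = c0
            order, fst = k
            for po, pf, ev, c in all_predecessors(order, fst, costs, genome):
                if len(po) < target:
                    continue
                nc = c0 + c
                if nc > min_sol:
                    continue
                nk = (po, pf)
                old = dist.get(nk)
                if old is None or nc < old:
                    dist[nk] = nc
                    bp[nk] = [(k, ev)]
                    nxt[nk] = None
                elif nc == old and (k, ev) not in bp[nk]:
                    bp[nk].append((k, ev))
        frontier = list(nxt)

    min_cost = None if math.isinf(min_sol) else min_sol
    solutions = sorted((k for k, c in sols.items() if c == min_cost), key=skey)
    return SearchResult(
        min_cost=min_cost,
        solutions=solutions,
        backpointers=bp,
        dist=dist,
        starts=[(o, forest) for o in start_orders],
        target=target,
        overflowed=overflowed,
        solutions_capped=capped,
    )
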