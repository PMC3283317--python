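"""Independent brute-force oracles used by the test suite.

Everything here is deliberately simple and exhaustive: forward enumeration
over the event semantics, plain breadth-first search for the ID distance,
and full enumeration of reconciliation mappings.  The oracles share only the
forward event semantics (`apply_event`) with the package -- never the
backward search, the reconciliation code or the ID-distance implementation
they are used to check.
"""

from __future__ import annotations

import heapq
import itertools

from tagevol.model import (
    Event,
    GeneTree,
    SpeciesTree,
    apply_event,
    event_cost,
    is_leaf,
    node_children,
    node_label,
    single_gene_state,
)
from tagevol.search import forest_to_state, state_signature


def strip_virtual(node):
    """Forest roots of a state built by forest_to_state."""
    if isinstance(node, str):
        return [node]
    if node[1].startswith("__virt"):
        out = []
        for c in node[2]:
            out.extend(strip_virtual(c))
        return out
    return [node]


def forward_event_catalogue(n: int, include_compound: bool = True):
    """Every graph event applicable to an order of length ``n`` (duplication,
    inverted duplication, inversion, and the compound duplications-with-
    deletion whose deleted run stays inside one copy block)."""
    for m in range(1, n + 1):
        for p in range(1, n - m + 2):
            yield Event("dup", "*", (p, p + m - 1))
            yield Event("idup", "*", (p, p + m - 1), variant="left")
            yield Event("idup", "*", (p, p + m - 1), variant="right")
            yield Event("inv", "*", (p, p + m - 1))
            if include_compound and m >= 2:
                for a in range(p, p + 2 * m):
                    for b in range(a, p + 2 * m):
                        d = b - a + 1
                        if d > m - 1:
                            continue
                        if (a - p < m) != (b - p < m):
                            continue  # run must stay within one copy block
                        yield Event("dup", "*", (p, p + m - 1), deleted_subspan=(a, b))
                        yield Event(
                            "idup", "*", (p, p + m - 1), variant="left", deleted_subspan=(a, b)
                        )
                        yield Event(
                            "idup", "*", (p, p + m - 1), variant="right", deleted_subspan=(a, b)
                        )


def forward_min_cost(target_order, target_forest, costs, cost_bound):
    """Dijkstra over forward histories from a single ancestral gene (either
    sign) to the target state, pruned at ``cost_bound``.  Returns the minimum
    cost, or None if nothing within the bound reaches the target.

    Admissible pruning: reaching the target from ``n`` genes requires at
    least one duplication covering the whole gene deficit, and a state that
    already has the right gene count but the wrong arrangement needs at
    least one inversion (the only count-preserving event).
    """
    from tagevol.model import OrderedGeneTreeSet

    target_sig = state_signature(target_order, target_forest)
    target_n = len(target_order)
    grow_alpha = min(costs.alpha["dup"], costs.alpha["idup"])
    grow_beta = min(costs.beta["dup"], costs.beta["idup"])
    inv_min = costs.alpha["inv"] + costs.beta["inv"]

    def h(n_genes):
        k = target_n - n_genes
        return 0.0 if k <= 0 else grow_alpha + k * grow_beta

    heap = []
    counter = itertools.count()
    for sign in (1, -1):
        st = single_gene_state("g", "*", sign)
        heapq.heappush(heap, (0.0, next(counter), st.orders["*"], st.tree))
    best = {}
    while heap:
        cost, _, order, tree = heapq.heappop(heap)
        sig = state_signature(order, frozenset(strip_virtual(tree)))
        if sig == target_sig:
            return cost
        if cost > best.get(sig, float("inf")):
            continue
        n = len(order)
        state = OrderedGeneTreeSet(tree=tree, orders={"*": order})
        for ev in forward_event_catalogue(n):
            grow = 0 if ev.etype == "inv" else ev.size - ev.del_size
            if n + grow > target_n:
                continue  # no event ever shrinks the cluster
            nc = cost + event_cost(ev, costs)
            if nc + h(n + grow) > cost_bound:
                continue
            child = apply_event(state, ev)
            corder = child.orders["*"]
            nsig = state_signature(corder, frozenset(strip_virtual(child.tree)))
            if len(corder) == target_n and nsig != target_sig and nc + inv_min > cost_bound:
                continue  # only inversions preserve the gene count
            if nc < best.get(nsig, float("inf")):
                best[nsig] = nc
                heapq.heappush(heap, (nc, next(counter), corder, child.tree))
    return None


def bfs_id_distance(x, y, max_depth: int = 12):
    """Plain BFS minimum number of inversions+deletions turning x into y.
    Deletions are only attempted on spans free of genes needed by y (such a
    deletion can never help)."""
    if x == y:
        return 0
    needed = {g for g, _ in y}
    frontier = [x]
    seen = {x}
    for depth in range(1, max_depth + 1):
        nxt = []
        for state in frontier:
            n = len(state)
            for p in range(n):
                for q in range(p, n):
                    inv = (
                        state[:p]
                        + tuple((g, -s) for g, s in reversed(state[p : q + 1]))
                        + state[q + 1 :]
                    )
                    if inv == y:
                        return depth
                    if inv not in seen:
                        seen.add(inv)
                        nxt.append(inv)
            for p in range(n):
                if state[p][0] in needed:
                    continue
                for q in range(p, n):
                    if state[q][0] in needed:
                        break
                    dele = state[:p] + state[q + 1 :]
                    if dele == y:
                        return depth
                    if dele not in seen:
                        seen.add(dele)
                        nxt.append(dele)
        frontier = nxt
    raise AssertionError("BFS oracle depth exhausted")


def brute_min_dup_loss(gene_tree: GeneTree, species_tree: SpeciesTree) -> int:
    """Minimum duplications+losses over all reconciliation mappings (each
    internal gene vertex may map to any species vertex that is an ancestor of
    both children's images)."""
    st = species_tree
    parent = st.parent_map()
    depth = st.depth_map()

    def ancestors(v):
        out = [v]
        while v in parent:
            v = parent[v]
            out.append(v)
        return out

    internals = []
    kids_of = {}
    leaf_img = {}

    def walk(n):
        lab = node_label(n)
        if is_leaf(n):
            leaf_img[lab] = gene_tree.leaf_genomes[n]
            return lab
        a, b = node_children(n)
        internals.append(lab)
        kids_of[lab] = (walk(a), walk(b))
        return lab

    root = walk(gene_tree.root)

    def dist(a, b):  # a ancestor of b
        d = 0
        while b != a:
            b = parent[b]
            d += 1
        return d

    def child_towards(s, img):
        """The child branch of internal vertex ``s`` containing ``img``
        (None when img == s)."""
        if img == s:
            return None
        while parent[img] != s:
            img = parent[img]
        return img

    best = None
    # candidate images: any species vertex; validity checked below
    all_vertices = list(st.postorder())
    for combo in itertools.product(all_vertices, repeat=len(internals)):
        m = dict(zip(internals, combo))
        m.update(leaf_img)
        ok = True
        cost = 0
        for lab in internals:
            a, b = kids_of[lab]
            for c in (a, b):
                # m[lab] must be an ancestor-or-equal of m[c]
                if m[lab] not in ancestors(m[c]):
                    ok = False
                    break
            if not ok:
                break
            # a vertex is a speciation only when its children enter two
            # different child branches of its image; otherwise it duplicates
            spec = (
                m[a] != m[lab]
                and m[b] != m[lab]
                and child_towards(m[lab], m[a]) != child_towards(m[lab], m[b])
            )
            if not spec:
                cost += 1
            for c in (a, b):
                d = dist(m[lab], m[c])
                cost += d if not spec else d - 1
        if ok and (best is None or cost < best):
            best = cost
    return best
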