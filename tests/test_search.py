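"""Backward neighbourhoods and the best-first search."""

import itertools
import random

import pytest

from tagevol.model import (
    DEFAULT_COSTS,
    CostModel,
    Event,
    ModelError,
    apply_event,
    event_cost,
)
from tagevol.search import (
    SearchParams,
    all_predecessors,
    backward_search,
    duplication_predecessors,
    duplication_with_deletion_predecessors,
    forest_to_state,
    inversion_predecessors,
    inverted_duplication_predecessors,
    state_signature,
)

from conftest import N
from oracles import forward_event_catalogue, forward_min_cost, strip_virtual


class TestNeighbourhoodExamples:
    def test_duplication_undo_simple(self):
        preds = duplication_predecessors(
            (("a", 1), ("b", 1)), frozenset({N("u", "a", "b")})
        )
        assert len(preds) == 1
        order, forest, ev = preds[0]
        assert order == (("u", 1),) and ev.etype == "dup" and ev.span == (1, 1)

    def test_duplication_undo_size_two_interleaved(self):
        forest = frozenset({N("r", N("ua", "a", "a2"), N("ub", "b", "b2"))})
        preds = duplication_predecessors(
            (("a", 1), ("b", 1), ("a2", 1), ("b2", 1)), forest
        )
        two = [p for p in preds if p[2].size == 2]
        assert len(two) == 1
        assert two[0][0] == (("ua", 1), ("ub", 1))

    def test_duplication_undo_rejects_sign_mismatch(self):
        preds = duplication_predecessors(
            (("a", 1), ("b", -1)), frozenset({N("u", "a", "b")})
        )
        assert preds == []

    def test_inverted_duplication_undo(self):
        forest = frozenset({N("u", "a", "b")})
        preds = inverted_duplication_predecessors((("a", -1), ("b", 1)), forest)
        by_variant = {p[2].variant: p[0] for p in preds}
        assert by_variant["left"] == (("u", 1),)
        assert by_variant["right"] == (("u", -1),)

    def test_inverted_duplication_undo_inside_context(self):
        forest = frozenset({"a", N("u", "b", "c")})
        preds = inverted_duplication_predecessors(
            (("a", 1), ("c", -1), ("b", 1)), forest
        )
        assert ((("a", 1), ("u", 1))) in [p[0] for p in preds]

    def test_no_inverted_undo_without_negated_block(self):
        preds = inverted_duplication_predecessors(
            (("a", 1), ("b", 1)), frozenset({N("u", "a", "b")})
        )
        assert preds == []

    def test_inversion_undo_enumerates_all_spans(self):
        order = (("a", 1), ("b", -1))
        preds = inversion_predecessors(order, frozenset({N("u", "a", "b")}))
        assert len(preds) == 3  # n(n+1)/2
        assert {p[0] for p in preds} == {
            (("a", -1), ("b", -1)),
            (("a", 1), ("b", 1)),
            (("b", 1), ("a", -1)),
        }

    def test_compound_undo_with_sibling_of_cherry(self):
        # cherry (a,b) with c sibling of the cherry root
        forest = frozenset({N("r", N("A", "a", "b"), "c")})
        preds = duplication_with_deletion_predecessors(
            (("a", 1), ("b", 1), ("c", 1)), forest
        )
        assert preds, "expected a dup-with-deletion undo"
        costs = [event_cost(ev, DEFAULT_COSTS) for _, _, ev in preds]
        assert (102 + 501) in costs
        match = [p for p in preds if event_cost(p[2]) == 603]
        order, _, ev = match[0]
        assert len(order) == 2 and ev.etype == "dup" and ev.del_size == 1

    def test_single_gene_has_no_compound_undo(self):
        assert duplication_with_deletion_predecessors((("a", 1),), frozenset({"a"})) == []


class TestNeighbourhoodSoundnessCompleteness:
    """One-event soundness/completeness against exhaustive forward
    enumeration from small ancestors (the full two-event sweep lives in the
    acceptance suite)."""

    @pytest.mark.parametrize("k", [2, 3])
    def test_single_event_exact(self, k):
        genes = [f"u{i}" for i in range(k)]
        for signs in itertools.product((1, -1), repeat=k):
            order = tuple(zip(genes, signs))
            forest = frozenset(genes)
            state = forest_to_state(order, forest)
            sig0 = state_signature(order, forest)
            for ev in forward_event_catalogue(k):
                if ev.etype == "inv":
                    continue  # involution; covered by the example test
                child = apply_event(state, ev)
                corder = child.orders["*"]
                cforest = frozenset(strip_virtual(child.tree))
                if ev.deleted_subspan is not None:
                    preds = duplication_with_deletion_predecessors(corder, cforest)
                elif ev.etype == "dup":
                    preds = duplication_predecessors(corder, cforest)
                else:
                    preds = inverted_duplication_predecessors(corder, cforest)
                # completeness: the ancestor appears among the undos
                assert any(
                    state_signature(po, pf) == sig0 for po, pf, _ in preds
                ), (order, ev)
                # soundness: every undo replays forward to the child
                for po, pf, pe in preds:
                    redo = apply_event(forest_to_state(po, pf), pe)
                    assert state_signature(
                        redo.orders["*"], frozenset(strip_virtual(redo.tree))
                    ) == state_signature(corder, cforest)


class TestNeighbourhoodSizes:
    def _random_state(self, rng, n_events):
        """A state grown by random forward events (so cherries exist)."""
        from tagevol.model import single_gene_state

        state = single_gene_state("g", "*")
        for _ in range(n_events):
            n = len(state.orders["*"])
            etype = rng.choice(["dup", "idup", "inv"])
            m = rng.randint(1, min(3, n))
            p = rng.randint(1, n - m + 1)
            variant = rng.choice(["left", "right"]) if etype == "idup" else None
            state = apply_event(state, Event(etype, "*", (p, p + m - 1), variant=variant))
        order = state.orders["*"]
        return order, frozenset(strip_virtual(state.tree))

    def test_complexity_guards(self):
        rng = random.Random(7)
        for trial in range(30):
            order, forest = self._random_state(rng, rng.randint(2, 4))
            n = len(order)
            if n > 12:
                continue
            inv = inversion_predecessors(order, forest)
            assert len(inv) == n * (n + 1) // 2
            dup = duplication_predecessors(order, forest)
            idup = inverted_duplication_predecessors(order, forest)
            assert len(dup) + len(idup) <= 4 * n
            comp = duplication_with_deletion_predecessors(order, forest)
            assert len(comp) <= 8 * n * n


class TestBackwardSearch:
    ABC_FOREST = frozenset({N("r", "a", N("x", "b", "c"))})

    def test_collapse_to_single_gene(self):
        res = backward_search((("a", 1), ("b", 1), ("c", 1)), self.ABC_FOREST, 1)
        assert res.min_cost == 202
        assert [s[0] for s in res.solutions] == [(("r", 1),)]
        events, idx = res.extract_path(res.solutions[0])
        assert [e.etype for e in events] == ["dup", "dup"] and idx == 0

    def test_stop_immediately_at_target(self):
        order = (("a", 1), ("b", 1), ("c", 1))
        res = backward_search(order, self.ABC_FOREST, 3)
        assert res.min_cost == 0 and res.solutions[0][0] == order

    def test_mixed_inverted_duplication_path(self):
        res = backward_search((("a", 1), ("c", -1), ("b", 1)), self.ABC_FOREST, 1)
        assert res.min_cost == 202  # one inverted duplication + one duplication

    def test_invalid_target_rejected(self):
        with pytest.raises(ModelError):
            backward_search((("a", 1),), frozenset({"a"}), 2)
        with pytest.raises(ModelError):
            backward_search((("a", 1),), frozenset({"a"}), 0)

    def test_no_predecessors_with_everything_disabled(self):
        costs = CostModel(
            alpha=DEFAULT_COSTS.alpha, beta=DEFAULT_COSTS.beta, enabled=frozenset({"inv"})
        )
        res = backward_search((("a", 1), ("b", 1)), frozenset({N("u", "a", "b")}), 1, costs)
        assert res.min_cost is None and res.solutions == []

    def test_min_matches_forward_enumeration_on_random_instances(self):
        """Spot check against the exhaustive forward oracle (bulk run in the
        acceptance suite)."""
        rng = random.Random(3)
        params = SearchParams(queue_capacity=10**6)
        from tagevol.model import single_gene_state

        for trial in range(8):
            state = single_gene_state("g", "*")
            cost_true = 0.0
            for _ in range(rng.randint(1, 3)):
                n = len(state.orders["*"])
                if n > 5:
                    break
                evs = [
                    e
                    for e in forward_event_catalogue(n)
                    if n + (0 if e.etype == "inv" else e.size - e.del_size) <= 6
                ]
                ev = evs[rng.randrange(len(evs))]
                state = apply_event(state, ev)
                cost_true += event_cost(ev)
            order = state.orders["*"]
            forest = frozenset(strip_virtual(state.tree))
            res = backward_search(order, forest, 1, DEFAULT_COSTS, params)
            opt = forward_min_cost(order, forest, DEFAULT_COSTS, cost_true)
            assert res.min_cost == opt, (order, res.min_cost, opt)
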