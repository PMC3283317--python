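"""Loss reinsertion, ID distance and the multi-species gluing algorithm."""

import math
import random

import pytest

from tagevol.model import (
    DEFAULT_COSTS,
    CostModel,
    Event,
    GeneTree,
    History,
    ModelError,
    SpeciesTree,
    single_gene_state,
    validate_history,
)
from tagevol.multispecies import (
    ExtensionOverflow,
    _apply_ops,
    branch_event_report,
    duplication_size_counts,
    extend_with_losses,
    id_distance,
    infer_history,
)
from tagevol.simulate import EventSpec, SimulationConfig, named_design, simulate_history

from conftest import N
from oracles import bfs_id_distance


class TestExtendWithLosses:
    @pytest.mark.parametrize(
        "order,lost,expected",
        [
            ((("a", 1),), ["b"], 4),
            ((("a", 1), ("c", 1)), ["b"], 6),
            ((("a", 1),), [], 1),
            ((("a", 1),), ["b", "c"], 24),  # (1+2)!/1! * 2**2
        ],
    )
    def test_closure_size(self, order, lost, expected):
        out = extend_with_losses(order, lost)
        assert len(out) == expected
        for o in out:
            assert len(o) == len(order) + len(lost)
            assert [g for g, _ in o if g not in lost] == [g for g, _ in order]

    def test_overflow_guard(self):
        order = tuple((f"g{i}", 1) for i in range(6))
        with pytest.raises(ExtensionOverflow):
            extend_with_losses(order, [f"l{i}" for i in range(4)], cap=1000)

    def test_lost_gene_already_present_rejected(self):
        with pytest.raises(ModelError):
            extend_with_losses((("a", 1),), ["a"])


class TestIDDistance:
    def test_identity(self):
        x = (("a", 1), ("b", -1))
        assert id_distance(x, x).count == 0

    def test_single_deletion(self):
        r = id_distance((("a", 1), ("b", 1)), (("a", 1),))
        assert r.count == 1 and r.events[0].etype == "del"

    def test_single_inversion(self):
        r = id_distance((("a", 1), ("b", -1), ("c", 1)), (("a", 1), ("b", 1), ("c", 1)))
        assert r.count == 1 and r.events[0].etype == "inv" and r.events[0].span == (2, 2)

    def test_events_realise_the_distance(self):
        rng = random.Random(1)
        for _ in range(50):
            n = rng.randint(2, 6)
            x = tuple((f"g{i}", rng.choice((1, -1))) for i in range(n))
            keep = sorted(rng.sample(range(n), rng.randint(1, n)))
            y = tuple(x[i] for i in keep)
            r = id_distance(x, y)
            assert _apply_ops(x, r.events) == y
            assert r.count == len(r.events)

    def test_agrees_with_bfs_oracle(self):
        rng = random.Random(2)
        for _ in range(40):
            n = rng.randint(2, 6)
            x = tuple((f"g{i}", rng.choice((1, -1))) for i in range(n))
            y = x
            for _ in range(rng.randint(1, 3)):
                p = rng.randint(1, len(y))
                q = rng.randint(p, len(y))
                y = (
                    y[: p - 1]
                    + tuple((g, -s) for g, s in reversed(y[p - 1 : q]))
                    + y[q:]
                )
            assert id_distance(x, y).count == bfs_id_distance(x, y)

    def test_target_with_foreign_gene_rejected(self):
        with pytest.raises(ModelError):
            id_distance((("a", 1),), (("z", 1),))

    def test_restricted_operations(self):
        x = (("a", 1), ("b", -1))
        y = (("a", 1), ("b", 1))
        assert math.isinf(id_distance(x, y, ops=("del",)).count)
        assert id_distance(x, y, ops=("inv",)).count == 1
        # deletions alone suffice when only content changes
        assert id_distance(x, (("a", 1),), ops=("del",)).count == 1

    def test_beyond_exact_bound_flags_heuristic(self):
        x = tuple((f"g{i}", 1) for i in range(10))
        y = x[:4]
        r = id_distance(x, y, exact_bound=8)
        assert not r.exact and r.count >= 1
        assert _apply_ops(x, r.events) == y


class TestInferHistoryExamples:
    def test_congruent_two_genome_cluster(self, congruent_instance):
        gt, orders, st = congruent_instance
        res = infer_history(gt, orders, st)
        assert res.solution_sets["A"] == [(("u", 1), ("v", 1))]
        assert res.branch_cost == 101  # one simple duplication above the root
        assert res.id_event_cost == 0 and res.id_label_total == 0
        assert res.validation.ok
        kinds = [e.etype for e in res.history.events]
        assert kinds == ["dup", "spec"]

    def test_loss_instance_extends_and_labels_edges(self, two_species):
        gt = GeneTree(
            root=N("r", N("x", "a1", "a2"), "b2"),
            leaf_genomes={"a1": "1", "a2": "2", "b2": "2"},
        )
        orders = {"1": (("a1", 1),), "2": (("a2", 1), ("b2", 1))}
        res = infer_history(gt, orders, two_species)
        # PG(1) has one gene, one loss on branch (A,1): E(A) is the union of
        # the 4 loss-extended orders with the right-branch ancestral order
        assert len(res.solution_sets["A"]) == 4
        assert res.branch_cost == 101
        assert res.id_label_total == 1  # one deletion on the edge towards 1
        assert res.chosen_edges[("A", "2")][2].count == 0
        assert res.chosen_edges[("A", "1")][2].count == 1
        assert res.validation.ok

    def test_events_only_above_root_cost_all_on_root_lineage(self, two_species):
        """A history whose events all precede the first speciation yields
        zero branch costs below the root and a total equal to the
        root-lineage cost."""
        cfg = SimulationConfig(
            species_tree=two_species,
            branch_events={"A": [EventSpec("dup"), EventSpec("dup"), EventSpec("idup")]},
            seed=13,
        )
        history, state, gene_tree = simulate_history(cfg)
        res = infer_history(gene_tree, dict(state.orders), two_species)
        assert res.branch_costs["1"] == 0 and res.branch_costs["2"] == 0
        assert res.branch_cost == res.branch_costs["A"]
        assert res.id_event_cost == 0
        assert res.validation.ok
        from tagevol.model import history_cost

        true_cost = history_cost(history.events)
        assert res.branch_cost <= true_cost

    def test_inference_requires_consistent_inputs(self, two_species):
        gt = GeneTree(root=N("r", "a1", "a2"), leaf_genomes={"a1": "1", "a2": "2"})
        with pytest.raises(ModelError):
            infer_history(gt, {"1": (("a1", 1),)}, two_species)  # genome 2 missing
        with pytest.raises(ModelError):
            infer_history(
                gt, {"1": (("zz", 1),), "2": (("a2", 1),)}, two_species
            )  # gene universe mismatch


class TestTracebackValidity:
    @pytest.mark.parametrize("seed", [11, 21, 31])
    def test_simulated_round_trip(self, seed):
        cfg = named_design("fig6", leaves=2, x=4, inversion_fraction=0.5, seed=seed)
        history, state, gene_tree = simulate_history(cfg)
        res = infer_history(gene_tree, dict(state.orders), cfg.species_tree)
        assert res.validation.ok
        # independently re-validate the traced-back history
        assert validate_history(res.history, state.orders, gene_tree).ok

    def test_four_species(self):
        cfg = named_design("fig6", leaves=4, x=4, inversion_fraction=0.0, seed=3)
        history, state, gene_tree = simulate_history(cfg)
        res = infer_history(gene_tree, dict(state.orders), cfg.species_tree)
        assert res.validation.ok
        inferred = sum(duplication_size_counts(res.history).values())
        assert inferred == 4

    def test_optimality_bound_on_small_instances(self):
        """Inferred total branch cost never exceeds the true history's cost
        when the queue never overflows."""
        from tagevol.model import history_cost

        for seed in (1, 2, 3, 4, 5):
            cfg = named_design("fig6", leaves=2, x=2, inversion_fraction=0.0, seed=seed)
            history, state, gene_tree = simulate_history(cfg)
            res = infer_history(gene_tree, dict(state.orders), cfg.species_tree)
            overflow = any(r.overflowed for r in res.branch_results.values())
            if not overflow:
                assert res.branch_cost + res.id_event_cost <= history_cost(history.events)


class TestReports:
    def test_branch_event_report_counting_conventions(self, two_species):
        events = [
            Event("dup", "A", (1, 1), branch="A"),
            Event("spec", "A", children=("1", "2"), branch="A"),
            Event("del", "1", (1, 2), branch="1"),  # size-2 deletion
            Event("dup", "2", (1, 1), deleted_subspan=(2, 2), branch="2"),
        ]
        hist = History(single_gene_state("g", "A"), [], two_species)
        hist.events = events
        frame = branch_event_report(hist).set_index("branch")
        assert frame.loc["A", "dup"] == 1 and frame.loc["A", "del"] == 0
        # one deletion event, two gene losses
        assert frame.loc["1", "del"] == 1 and frame.loc["1", "gene_losses"] == 2
        # the compound counts as one duplication plus one deletion/one loss
        assert frame.loc["2", "dup"] == 1
        assert frame.loc["2", "del"] == 1 and frame.loc["2", "gene_losses"] == 1

    def test_duplication_size_histogram(self):
        hist = History(single_gene_state("g", "G"), [])
        hist.events = [
            Event("dup", "G", (1, 1)),
            Event("dup", "G", (1, 2)),
            Event("idup", "G", (1, 2), variant="left"),
            Event("inv", "G", (1, 2)),
        ]
        sizes = duplication_size_counts(hist)
        assert dict(sizes) == {1: 1, 2: 2}


class TestDisabledEvents:
    def test_inversion_free_inference(self, congruent_instance):
        """With inversions and inverted duplications disabled (deleterious in
        head-to-head clusters), the congruent instance still resolves."""
        gt, orders, st = congruent_instance
        costs = CostModel(
            alpha=DEFAULT_COSTS.alpha,
            beta=DEFAULT_COSTS.beta,
            enabled=frozenset({"dup", "del"}),
        )
        res = infer_history(gt, orders, st, costs=costs)
        assert res.validation.ok and res.branch_cost == 101
        assert all(e.etype not in ("inv", "idup") for e in res.history.events)
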