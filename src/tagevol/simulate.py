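"""Forward simulation of cluster histories consistent with a species tree.

Starting from a single positive ancestral gene, the simulator traverses the
species tree root-to-leaves.  On every branch (including the lineage above
the root speciation) it applies the branch's event budget -- duplications,
inverted duplications, inversions, deletions -- in a random order, then a
speciation at each internal vertex.  Event sizes are drawn from a geometric
distribution truncated by the current cluster size (small events are more
frequent in real clusters); positions are uniform among valid spans.

Three named experimental designs are provided for a balanced species tree
with ``L`` leaves (root-to-leaf branch count ``d = log2(L) + 1``, counting
the pre-root lineage):

- ``fig5``: ``n`` single and ``n`` double tandem duplications plus 2
  inversions per branch -- the only design with fixed duplication sizes, so
  every extant genome holds exactly ``3*d*n + 1`` genes;
- ``fig6``: a total of ``x`` duplications (half direct, half inverted)
  together with ``0``, ``x/2`` or ``x`` inversions, spread evenly over the
  branches (round-robin for remainders);
- ``fig7``: 4 tandem duplications, 1 inverted duplication, 1 inversion and
  1 deletion of size 1 or 2 on each branch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from tagevol.model import (
    Event,
    GeneTree,
    History,
    ModelError,
    OrderedGeneTreeSet,
    SpeciesTree,
    apply_event,
    single_gene_state,
)

__all__ = [
    "EventSpec",
    "SimulationConfig",
    "SimulationError",
    "balanced_species_tree",
    "named_design",
    "sample_event_size",
    "simulate_history",
]


class SimulationError(ModelError):
    """Raised when a branch budget cannot be realised (e.g. a deletion that
    would empty a genome, repeatedly)."""


@dataclass(frozen=True)
class EventSpec:
    """One budgeted event on a branch: fixed ``size`` or sampled when None
    (``max_size`` further truncates the sampling, e.g. deletions of size at
    most 2)."""

    etype: str
    size: int | None = None
    max_size: int | None = None


@dataclass
class SimulationConfig:
    """Simulation inputs: the species tree, one event list per branch (keyed
    by the branch's lower vertex; the root vertex keys the pre-root lineage),
    the truncated-geometric size parameter and the seed."""

    species_tree: SpeciesTree
    branch_events: Mapping[str, Sequence[EventSpec]]
    size_p: float = 0.5
    seed: int = 0
    shuffle: bool = True
    name: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.size_p < 1.0):
            raise SimulationError("size_p must lie in (0, 1)")
        known = set(self.species_tree.postorder())
        for v in self.branch_events:
            if v not in known:
                raise SimulationError(f"unknown branch vertex {v!r}")


def sample_event_size(p: float, max_size: int, rng: np.random.Generator) -> int:
    """Draw from a geometric distribution of parameter ``p`` truncated (and
    renormalised) to ``1..max_size``."""
    if max_size < 1:
        raise SimulationError("max_size must be >= 1")
    if max_size == 1:
        return 1
    w = np.array([(1.0 - p) ** (k - 1) * p for k in range(1, max_size + 1)])
    w /= w.sum()
    return int(rng.choice(np.arange(1, max_size + 1), p=w))


def simulate_history(
    config: SimulationConfig,
) -> tuple[History, OrderedGeneTreeSet, GeneTree]:
    """Simulate one history; returns the full true history, the final leaf
    state and the final gene tree.  Deterministic given the config seed."""
    st = config.species_tree
    rng = np.random.default_rng(config.seed)
    state = single_gene_state(gene_id="g", genome=st.root)
    events: list[Event] = []

    def do_branch(vertex: str) -> None:
        nonlocal state
        queue = list(config.branch_events.get(vertex, ()))
        if config.shuffle and len(queue) > 1:
            queue = [queue[i] for i in rng.permutation(len(queue))]
        retries = 0
        while queue:
            spec = queue.pop(0)
            n = len(state.orders[vertex])
            hi = n - 1 if spec.etype == "del" else n
            if spec.max_size is not None:
                hi = min(hi, spec.max_size)
            infeasible = hi < 1 or (spec.size is not None and spec.size > hi)
            if infeasible:
                # deferred behind later growth (e.g. a deletion, or a fixed
                # double duplication, while the cluster is still a single gene)
                retries += 1
                if retries > len(queue) + 2:
                    raise SimulationError(
                        f"event budget on branch {vertex!r} cannot be realised "
                        f"({spec.etype} of size {spec.size or '>=1'} on {n} genes)"
                    )
                queue.append(spec)
                continue
            retries = 0
            size = spec.size if spec.size is not None else sample_event_size(
                config.size_p, hi, rng
            )
            pos = int(rng.integers(1, n - size + 2))
            variant = None
            if spec.etype == "idup":
                variant = "left" if rng.integers(2) == 0 else "right"
            ev = Event(
                spec.etype, vertex, (pos, pos + size - 1), variant=variant, branch=vertex
            )
            state = apply_event(state, ev)
            events.append(ev)

    def walk(vertex: str) -> None:
        nonlocal state
        do_branch(vertex)
        if not st.is_leaf(vertex):
            kids = st.children[vertex]
            ev = Event("spec", vertex, children=kids, branch=vertex)
            state = apply_event(state, ev)
            events.append(ev)
            for k in kids:
                walk(k)

    walk(st.root)
    history = History(
        initial=single_gene_state(gene_id="g", genome=st.root),
        events=events,
        species_tree=st,
    )
    gene_tree = GeneTree(root=state.tree, leaf_genomes=state.genome_of())
    return history, state, gene_tree


# ---------------------------------------------------------------------------
# named designs
# ---------------------------------------------------------------------------


def balanced_species_tree(leaves: int) -> SpeciesTree:
    """Balanced binary species tree with ``leaves`` (a power of two) extant
    genomes named '1'..'L'; internal vertices named by their leaf range."""
    if leaves < 2 or leaves & (leaves - 1):
        raise SimulationError("a balanced tree needs a power-of-two leaf count")
    children: dict[str, tuple[str, str]] = {}

    def build(lo: int, hi: int) -> str:
        if lo == hi:
            return str(lo)
        mid = (lo + hi) // 2
        name = f"a{lo}_{hi}"
        children[name] = (build(lo, mid), build(mid + 1, hi))
        return name

    root = build(1, leaves)
    return SpeciesTree(root=root, children=children)


def _branch_list(st: SpeciesTree) -> list[str]:
    """All branches in a deterministic preorder (root vertex = pre-root)."""
    out: list[str] = []

    def walk(v: str) -> None:
        out.append(v)
        for k in st.children.get(v, ()):
            walk(k)

    walk(st.root)
    return out


def named_design(
    name: str,
    leaves: int = 2,
    n: int = 1,
    x: int = 4,
    inversion_fraction: float = 0.0,
    p: float = 0.5,
    seed: int = 0,
) -> SimulationConfig:
    """Build the simulation config of one of the named designs (see module
    docstring).  ``inversion_fraction`` (fig6) must be 0, 1/3 or 1/2 -- the
    fraction of inversions among all simulated events."""
    st = balanced_species_tree(leaves)
    branches = _branch_list(st)
    budget: dict[str, list[EventSpec]] = {b: [] for b in branches}

    if name == "fig5":
        for b in branches:
            budget[b] += [EventSpec("dup", size=1)] * n
            budget[b] += [EventSpec("dup", size=2)] * n
            budget[b] += [EventSpec("inv")] * 2
    elif name == "fig6":
        if x % 2:
            raise SimulationError("fig6 needs an even total duplication count")
        frac_to_mult = {0.0: 0.0, 1 / 3: 0.5, 0.5: 1.0}
        key = min(frac_to_mult, key=lambda f: abs(f - inversion_fraction))
        if abs(key - inversion_fraction) > 1e-9:
            raise SimulationError("inversion_fraction must be 0, 1/3 or 1/2")
        n_inv = int(round(frac_to_mult[key] * x))
        specs = [EventSpec("dup")] * (x // 2) + [EventSpec("idup")] * (x - x // 2)
        specs += [EventSpec("inv")] * n_inv
        for i, spec in enumerate(specs):
            budget[branches[i % len(branches)]].append(spec)
    elif name == "fig7":
        for b in branches:
            budget[b] += [EventSpec("dup")] * 4
            budget[b] += [EventSpec("idup")]
            budget[b] += [EventSpec("inv")]
            budget[b] += [EventSpec("del", max_size=2)]
    else:
        raise SimulationError(f"unknown design {name!r}")

    return SimulationConfig(
        species_tree=st,
        branch_events=budget,
        size_p=p,
        seed=seed,
        name=name,
    )
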