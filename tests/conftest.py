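import pytest

from tagevol.model import GeneTree, SpeciesTree


def N(label, a, b):
    """Shorthand internal gene-tree node."""
    return ("N", label, frozenset((a, b)))


@pytest.fixture
def two_species():
    """Species tree (1,2)A."""
    return SpeciesTree(root="A", children={"A": ("1", "2")})


@pytest.fixture
def three_species():
    """Species tree ((1,2)A,3)B."""
    return SpeciesTree(root="B", children={"B": ("A", "3"), "A": ("1", "2")})


@pytest.fixture
def congruent_instance(two_species):
    """Two genomes, two genes each, gene tree congruent with one ancestral
    duplication: T = ((a1,a2)u,(b1,b2)v)."""
    gt = GeneTree(
        root=N("r", N("u", "a1", "a2"), N("v", "b1", "b2")),
        leaf_genomes={"a1": "1", "a2": "2", "b1": "1", "b2": "2"},
    )
    orders = {"1": (("a1", 1), ("b1", 1)), "2": (("a2", 1), ("b2", 1))}
    return gt, orders, two_species
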