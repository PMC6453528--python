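import pytest

from litrank.relations import RelationTriple, build_matrix
from litrank.synthetic import SyntheticSpec, generate


@pytest.fixture
def toy_triples():
    """A->B (2 articles) and B->C (1 article) over {A, B, C}."""
    return [
        RelationTriple("A", "Regulation", "B", 2),
        RelationTriple("B", "Regulation", "C", 1),
    ]


@pytest.fixture
def toy_matrix(toy_triples):
    return build_matrix(toy_triples)


@pytest.fixture
def saturated_ones():
    """4x4 all-ones count matrix (every ordered pair observed once)."""
    triples = [
        RelationTriple(a, "Regulation", t, 1) for a in "ABCD" for t in "ABCD"
    ]
    return build_matrix(triples)


@pytest.fixture(scope="session")
def planted():
    """A small planted-structure network shared across tests."""
    spec = SyntheticSpec(n_genes=120, n_known_downstream=10,
                         n_heldout_downstream=5, seed=11)
    truth = generate(spec)
    return truth, build_matrix(truth.edges)
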