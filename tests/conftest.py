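import warnings

import pytest

from tissue_enrichment import (
    AnnotationMap,
    Ontology,
    Term,
    fig1_fixture,
    FixtureParams,
    generate_fixture,
)


def make_ontology(edges, extra_terms=()):
    """Build an Ontology from {child: [parents]} plus optional rootless ids."""
    ids = set(edges) | {p for ps in edges.values() for p in ps} | set(extra_terms)
    return Ontology(
        Term(term_id=t, name=t, parents=frozenset(edges.get(t, ())))
        for t in sorted(ids)
    )


def edge_map(ont):
    """{child: set-of-parents} view of an ontology, for the oracles."""
    return {t: ont.parents(t) for t in ont.graph.nodes}


@pytest.fixture
def chain_ontology():
    """C -> B -> A with direct annotations C:{g1}, B:{g2}."""
    ont = make_ontology({"B": ["A"], "C": ["B"]})
    direct = AnnotationMap(
        gene_sets={"C": frozenset({"g1"}), "B": frozenset({"g2"})},
        flavor="direct",
    )
    return ont, direct


@pytest.fixture
def diamond_ontology():
    """D below both B and C, which share root A; only D is annotated."""
    ont = make_ontology({"B": ["A"], "C": ["A"], "D": ["B", "C"]})
    direct = AnnotationMap(gene_sets={"D": frozenset({"g1"})}, flavor="direct")
    return ont, direct


@pytest.fixture(scope="session")
def fig1():
    return fig1_fixture()


@pytest.fixture
def random_fixture():
    def _make(seed, **overrides):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return generate_fixture(FixtureParams(seed=seed, **overrides))

    return _make
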