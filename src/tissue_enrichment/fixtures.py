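"""Synthetic ontologies, annotations and gene lists with planted structure.

The generator emulates the structural features of a curated anatomy ontology
that the trimming filters and the enrichment test rely on:

- a rooted DAG with multi-parent nodes (parents are sampled from earlier
  nodes in a topological construction order, so acyclicity holds by
  construction rather than by rejection);
- direct annotations concentrated on leaves, with counts drawn from a
  discrete uniform distribution that includes sparsely annotated leaves, so
  inherited counts grow monotonically toward the root;
- planted near-identical sister pairs (the left/right neuron-pair analogue;
  Jaccard similarity >= 0.95) that the similarity filter should flag;
- an optional planted enriched term — a well-annotated leaf that is the only
  child of its parent — together with a query list drawn to overlap it
  heavily, so end-to-end recovery can be asserted against ground truth.

Every fixture carries a truth record naming the planted redundant pairs, the
under-annotated leaves, and the planted enriched term.  Identical seeds
reproduce identical fixtures byte for byte.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .ontology import AnnotationMap, Ontology, Term

__all__ = [
    "FixtureParams",
    "FixtureTruth",
    "Fixture",
    "generate_fixture",
    "fig1_fixture",
    "write_fixture",
]


@dataclass(frozen=True)
class FixtureParams:
    """Knobs of the synthetic-data generator.

    ``n_terms`` counts the core DAG only; planted structures add a few extra
    nodes.  ``leaf_count_low/high`` bound the discrete-uniform direct
    annotation count per core leaf.  ``reference_cutoff`` is only used to
    name under-annotated leaves in the truth record.
    """

    n_terms: int = 60
    max_children: int = 5
    multi_parent_prob: float = 0.1
    n_genes: int = 500
    leaf_count_low: int = 0
    leaf_count_high: int = 60
    n_redundant_sister_pairs: int = 2
    redundant_pair_size: int = 30
    plant_enriched: bool = True
    planted_term_size: int = 40
    query_overlap: float = 0.8
    query_noise: int = 5
    null_query_size: int = 30
    reference_cutoff: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_terms < 2:
            raise ValueError("n_terms must be >= 2")
        if self.max_children < 2:
            raise ValueError("max_children must be >= 2")
        if not 0 <= self.multi_parent_prob <= 1:
            raise ValueError("multi_parent_prob must lie in [0, 1]")
        if not 0 <= self.query_overlap <= 1:
            raise ValueError("query_overlap must lie in [0, 1]")
        if self.leaf_count_high < self.leaf_count_low or self.leaf_count_low < 0:
            raise ValueError("invalid leaf annotation-count bounds")
        needed = max(
            self.leaf_count_high,
            self.redundant_pair_size + 1,
            self.planted_term_size,
        )
        if self.n_genes < needed:
            raise ValueError(
                f"n_genes={self.n_genes} too small for the requested "
                f"annotation sizes (need >= {needed})"
            )


@dataclass
class FixtureTruth:
    """Ground truth planted into a fixture."""

    redundant_pairs: list[tuple[str, tuple[str, str]]]
    under_annotated_leaves: list[str]
    planted_term: str | None
    planted_genes: list[str]
    leaf_direct_counts: dict[str, int]


@dataclass
class Fixture:
    ontology: Ontology
    direct: AnnotationMap
    query: list[str]
    truth: FixtureTruth


def _term_id(i: int) -> str:
    return f"ANAT:{i:07d}"


def _gene_id(i: int) -> str:
    return f"gene-{i:04d}"


def generate_fixture(params: FixtureParams) -> Fixture:
    """Generate one synthetic (ontology, annotations, query, truth) tuple."""
    rng = np.random.default_rng(params.seed)
    pool = np.array([_gene_id(i) for i in range(params.n_genes)])

    # --- core DAG: node i picks parents among nodes < i -------------------
    parents: dict[int, set[int]] = {0: set()}
    child_count = [0] * params.n_terms
    for i in range(1, params.n_terms):
        eligible = [j for j in range(i) if child_count[j] < params.max_children]
        if not eligible:
            eligible = list(range(i))
        primary = int(rng.choice(eligible))
        chosen = {primary}
        if len(eligible) > 1 and rng.random() < params.multi_parent_prob:
            extra = int(rng.choice([j for j in eligible if j != primary]))
            chosen.add(extra)
        parents[i] = chosen
        for j in chosen:
            child_count[j] += 1

    next_id = params.n_terms
    names = {i: f"tissue {i}" for i in range(params.n_terms)}
    direct_sets: dict[int, frozenset[str]] = {}
    truth = FixtureTruth(
        redundant_pairs=[],
        under_annotated_leaves=[],
        planted_term=None,
        planted_genes=[],
        leaf_direct_counts={},
    )

    def add_node(name: str, parent_ids: set[int]) -> int:
        nonlocal next_id
        node = next_id
        next_id += 1
        parents[node] = set(parent_ids)
        names[node] = name
        return node

    # --- planted near-identical sister pairs ------------------------------
    for k in range(params.n_redundant_sister_pairs):
        anchor = int(rng.integers(0, params.n_terms))
        pair_parent = add_node(f"redundant parent {k}", {anchor})
        base = rng.choice(pool, size=params.redundant_pair_size + 1, replace=False)
        left = add_node(f"redundant left {k}", {pair_parent})
        right = add_node(f"redundant right {k}", {pair_parent})
        direct_sets[left] = frozenset(base)  # base plus one extra gene
        direct_sets[right] = frozenset(base[:-1])
        truth.redundant_pairs.append(
            (_term_id(pair_parent), (_term_id(left), _term_id(right)))
        )

    # --- planted enriched term: a well-annotated only-child leaf ----------
    planted_genes: np.ndarray | None = None
    if params.plant_enriched:
        anchor = int(rng.integers(0, params.n_terms))
        solo_parent = add_node("planted parent", {anchor})
        planted = add_node("planted enriched tissue", {solo_parent})
        planted_genes = rng.choice(
            pool, size=params.planted_term_size, replace=False
        )
        direct_sets[planted] = frozenset(planted_genes)
        truth.planted_term = _term_id(planted)
        truth.planted_genes = sorted(planted_genes.tolist())

    # --- direct annotations on the core leaves ----------------------------
    internal: set[int] = set()  # nodes that are a parent of something
    for ps in parents.values():
        internal |= ps
    for i in range(params.n_terms):
        if i in internal:
            continue  # internal node: annotations arrive by inheritance
        count = int(
            rng.integers(params.leaf_count_low, params.leaf_count_high + 1)
        )
        genes = rng.choice(pool, size=count, replace=False) if count else []
        direct_sets[i] = frozenset(genes)
        truth.leaf_direct_counts[_term_id(i)] = count
        if count < params.reference_cutoff:
            truth.under_annotated_leaves.append(_term_id(i))
    truth.under_annotated_leaves.sort()

    # --- assemble ---------------------------------------------------------
    terms = [
        Term(
            term_id=_term_id(i),
            name=names[i],
            parents=frozenset(_term_id(j) for j in parents[i]),
        )
        for i in sorted(parents)
    ]
    ontology = Ontology(terms)
    direct = AnnotationMap(
        gene_sets={
            _term_id(i): genes for i, genes in direct_sets.items() if genes
        },
        flavor="direct",
    )

    # --- query list --------------------------------------------------------
    if params.plant_enriched:
        assert planted_genes is not None
        n_hit = int(round(params.query_overlap * len(planted_genes)))
        hits = rng.choice(planted_genes, size=n_hit, replace=False)
        others = np.setdiff1d(pool, planted_genes, assume_unique=False)
        noise = rng.choice(others, size=params.query_noise, replace=False)
        query = sorted(set(hits.tolist()) | set(noise.tolist()))
    else:
        query = sorted(
            rng.choice(pool, size=params.null_query_size, replace=False).tolist()
        )

    return Fixture(ontology=ontology, direct=direct, query=query, truth=truth)


# ---------------------------------------------------------------------------
# The worked trimming example: a 7-term chain-and-branch DAG
# ---------------------------------------------------------------------------

#: Constructed per-term direct annotation counts for the worked example.
#: The three leaves sit below the 25-gene cutoff; the two keepers reach it
#: (gamma only through inheritance: 15 direct + 5 + 8 from its leaves = 28).
_FIG1_DIRECT_COUNTS = {
    "zeta": 5,
    "eta": 8,
    "epsilon": 10,
    "gamma": 15,
    "delta": 30,
}

_FIG1_EDGES = {
    "alpha": (),
    "beta": ("alpha",),
    "delta": ("alpha",),
    "gamma": ("beta",),
    "epsilon": ("beta",),
    "zeta": ("gamma",),
    "eta": ("gamma",),
}

_FIG1_IDS = {
    name: f"FIG:{i:07d}"
    for i, name in enumerate(
        ["alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta"], start=1
    )
}


def fig1_fixture() -> tuple[Ontology, AnnotationMap]:
    """The hand-built worked example for the trimming pipeline.

    Seven terms alpha..eta: at a 25-gene cutoff (similarity trimming
    disabled, S = 1) the annotation filter removes the under-annotated
    terminal terms epsilon, zeta and eta; the ceiling filter then removes
    alpha and beta, whose surviving daughters all pass; only gamma and delta
    enter the dictionary.  Annotation counts are constructed to match that
    behaviour (they are not part of any published record) and gene sets are
    pairwise disjoint, so no sister set is similarity-redundant.
    """
    terms = [
        Term(
            term_id=_FIG1_IDS[name],
            name=name,
            parents=frozenset(_FIG1_IDS[p] for p in ps),
        )
        for name, ps in _FIG1_EDGES.items()
    ]
    gene_sets: dict[str, frozenset[str]] = {}
    cursor = 0
    for name, count in _FIG1_DIRECT_COUNTS.items():
        gene_sets[_FIG1_IDS[name]] = frozenset(
            f"g{j:03d}" for j in range(cursor, cursor + count)
        )
        cursor += count
    return Ontology(terms), AnnotationMap(gene_sets=gene_sets, flavor="direct")


def fig1_term_ids() -> dict[str, str]:
    """Map the worked example's Greek names to their term ids."""
    return dict(_FIG1_IDS)


# ---------------------------------------------------------------------------
# File output, so the CLI can be smoke-tested end to end from files
# ---------------------------------------------------------------------------


def write_fixture(fixture: Fixture, out_dir: str) -> dict[str, str]:
    """Write fixture.obo, annotations.tsv, genes.txt and truth.json.

    All outputs are sorted, newline-terminated text, byte-stable for a given
    seed.  Returns the mapping of logical name -> path.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "obo": os.path.join(out_dir, "fixture.obo"),
        "annotations": os.path.join(out_dir, "annotations.tsv"),
        "genes": os.path.join(out_dir, "genes.txt"),
        "truth": os.path.join(out_dir, "truth.json"),
    }
    ont = fixture.ontology
    with open(paths["obo"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-anatomy\n")
        for term_id in ont.term_ids:
            term = ont[term_id]
            fh.write(f"\n[Term]\nid: {term.term_id}\nname: {term.name}\n")
            if term.obsolete:
                fh.write("is_obsolete: true\n")
            for parent in sorted(term.parents):
                fh.write(f"is_a: {parent} ! {ont.name(parent)}\n")
    with open(paths["annotations"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("term_id\tgene_id\n")
        for term_id in sorted(fixture.direct.gene_sets):
            for gene in sorted(fixture.direct.gene_sets[term_id]):
                fh.write(f"{term_id}\t{gene}\n")
    with open(paths["genes"], "w", encoding="utf-8", newline="\n") as fh:
        for gene in fixture.query:
            fh.write(f"{gene}\n")
    with open(paths["truth"], "w", encoding="utf-8", newline="\n") as fh:
        json.dump(asdict(fixture.truth), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
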