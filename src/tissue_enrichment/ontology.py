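"""Anatomy-ontology core: OBO parsing, the term DAG, and annotation inheritance.

The ontology is a rooted directed acyclic graph of anatomy terms whose
``is_a`` and ``part_of`` edges imply annotation inheritance: a gene annotated
to a term is implicitly annotated to every ancestor of that term, so inherited
annotation counts grow monotonically toward the root.  Both relation types are
treated identically for inheritance and for sisterhood.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping

import networkx as nx
import obonet

__all__ = [
    "Term",
    "Ontology",
    "AnnotationMap",
    "OboParseError",
    "OntologyValidationError",
    "AnnotationError",
    "parse_obo",
    "load_annotations",
    "propagate_annotations",
    "sister_sets",
]

#: Relationship types that imply annotation inheritance.  Everything else
#: (develops_from, regulates, ...) is ignored.
INHERITANCE_RELATIONS = ("is_a", "part_of")


class OboParseError(ValueError):
    """Raised when an OBO stanza cannot be interpreted."""


class OntologyValidationError(ValueError):
    """Raised when the term graph violates an ontology invariant."""


class AnnotationError(ValueError):
    """Raised when an annotation table row cannot be read."""


@dataclass(frozen=True)
class Term:
    """A single ontology term.

    Parameters
    ----------
    term_id
        Ontology accession (e.g. ``"WBbt:0005735"``); unique within an
        :class:`Ontology`.
    name
        Human-readable label.
    parents
        Term ids reachable by one ``is_a`` or ``part_of`` edge.  Empty for
        roots and for obsolete terms.
    obsolete
        Obsolete terms are parsed and kept for bookkeeping but excluded from
        the edge relation and from annotation propagation.
    """

    term_id: str
    name: str
    parents: frozenset[str] = frozenset()
    obsolete: bool = False


class Ontology:
    """A rooted DAG of terms connected by is_a/part_of edges.

    Multi-parent nodes and multiple roots are allowed.  Construction
    validates that term ids are unique, that every parent reference resolves
    to a known non-obsolete term, and that the edge relation is acyclic.
    """

    def __init__(self, terms: Iterable[Term]):
        self._terms: dict[str, Term] = {}
        for term in terms:
            if term.term_id in self._terms:
                raise OntologyValidationError(
                    f"duplicate term id {term.term_id!r}"
                )
            self._terms[term.term_id] = term

        # child -> parent edges, obsolete terms excluded entirely
        graph = nx.DiGraph()
        for term in self._terms.values():
            if term.obsolete:
                continue
            graph.add_node(term.term_id)
            for parent in term.parents:
                target = self._terms.get(parent)
                if target is None:
                    raise OntologyValidationError(
                        f"term {term.term_id!r} names unknown parent {parent!r}"
                    )
                if target.obsolete:
                    continue  # obsolete terms take part in no edges
                graph.add_edge(term.term_id, parent)
        try:
            cycle = nx.find_cycle(graph)
        except nx.NetworkXNoCycle:
            pass
        else:
            path = " -> ".join(str(edge[0]) for edge in cycle)
            raise OntologyValidationError(
                f"is_a/part_of relation contains a cycle: {path}"
            )
        self._graph = graph

    # -- basic accessors ---------------------------------------------------

    @property
    def graph(self) -> nx.DiGraph:
        """Child -> parent DiGraph over non-obsolete terms."""
        return self._graph

    def __len__(self) -> int:
        return len(self._terms)

    def __iter__(self) -> Iterator[str]:
        return iter(self._terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._terms

    def __getitem__(self, term_id: str) -> Term:
        return self._terms[term_id]

    @property
    def term_ids(self) -> list[str]:
        """All term ids, obsolete included, in sorted order."""
        return sorted(self._terms)

    @property
    def active_ids(self) -> list[str]:
        """Non-obsolete term ids in sorted order."""
        return sorted(self._graph.nodes)

    def name(self, term_id: str) -> str:
        return self._terms[term_id].name

    # -- graph queries -----------------------------------------------------

    def parents(self, term_id: str) -> set[str]:
        return set(self._graph.successors(term_id))

    def children(self, term_id: str) -> set[str]:
        return set(self._graph.predecessors(term_id))

    def descendants(self, term_id: str) -> set[str]:
        """Strict descendants along is_a/part_of chains."""
        return set(nx.ancestors(self._graph, term_id))

    def ancestors(self, term_id: str) -> set[str]:
        """Strict ancestors along is_a/part_of chains."""
        return set(nx.descendants(self._graph, term_id))

    @property
    def roots(self) -> set[str]:
        return {n for n in self._graph.nodes if self._graph.out_degree(n) == 0}

    @property
    def leaves(self) -> set[str]:
        return {n for n in self._graph.nodes if self._graph.in_degree(n) == 0}


@dataclass
class AnnotationMap:
    """Per-term gene sets, either as directly curated or after inheritance.

    ``flavor`` is ``"direct"`` for curated term/gene pairs as loaded, or
    ``"inherited"`` once annotations have been propagated to ancestors
    (``inherited[t]`` is the union of direct sets over ``t`` and all of its
    descendants).
    """

    gene_sets: dict[str, frozenset[str]]
    flavor: str = "direct"
    #: rows whose term id was absent from the ontology: (line_no, term, gene)
    orphans: tuple[tuple[int, str, str], ...] = ()

    def genes(self, term_id: str) -> frozenset[str]:
        return self.gene_sets.get(term_id, frozenset())

    def count(self, term_id: str) -> int:
        return len(self.gene_sets.get(term_id, ()))

    def __len__(self) -> int:
        return len(self.gene_sets)


# ---------------------------------------------------------------------------
# OBO parsing
# ---------------------------------------------------------------------------


def _as_stream(source: str | IO[str]) -> IO[str]:
    if isinstance(source, str):
        return open(source, "r", encoding="utf-8")
    return source


def _check_term_stanzas(text: str) -> None:
    """Reject [Term] stanzas that lack an ``id:`` line, naming the stanza."""
    stanza_no = 0
    in_term = False
    has_id = False
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("["):
            if in_term and not has_id:
                raise OboParseError(f"[Term] stanza #{stanza_no} has no id")
            in_term = line == "[Term]"
            if in_term:
                stanza_no += 1
                has_id = False
        elif in_term and line.startswith("id:"):
            has_id = True
    if in_term and not has_id:
        raise OboParseError(f"[Term] stanza #{stanza_no} has no id")


def parse_obo(source: str | IO[str]) -> Ontology:
    """Parse an OBO 1.2 flat file into an :class:`Ontology`.

    Recognizes ``id``, ``name``, ``is_a`` and ``relationship: part_of`` lines
    of ``[Term]`` stanzas; other relationship types are ignored.  Obsolete
    terms are kept but flagged and excluded from the edge relation.

    Parameters
    ----------
    source
        Path to an ``.obo`` file, or an open text stream.
    """
    stream = _as_stream(source)
    text = stream.read()
    _check_term_stanzas(text)
    try:
        graph = obonet.read_obo(io.StringIO(text), ignore_obsolete=False)
    except Exception as exc:  # obonet raises bare KeyError/ValueError
        raise OboParseError(f"malformed OBO input: {exc!r}") from exc

    terms = []
    obsolete = {
        node
        for node, data in graph.nodes(data=True)
        if str(data.get("is_obsolete", "false")).lower() == "true"
    }
    for node, data in graph.nodes(data=True):
        if node in obsolete:
            parents: frozenset[str] = frozenset()
        else:
            parents = frozenset(
                parent
                for _, parent, rel in graph.out_edges(node, keys=True)
                if rel in INHERITANCE_RELATIONS and parent not in obsolete
            )
        terms.append(
            Term(
                term_id=node,
                name=data.get("name", node),
                parents=parents,
                obsolete=node in obsolete,
            )
        )
    return Ontology(terms)


# ---------------------------------------------------------------------------
# Annotation loading
# ---------------------------------------------------------------------------

_TSV_HEADER_TOKENS = {"term", "term_id", "termid", "gene", "gene_id", "geneid"}


def _iter_tsv_rows(text: str) -> Iterator[tuple[int, str, str]]:
    first_data_row = True
    for line_no, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
            raise AnnotationError(
                f"line {line_no}: expected 'term<TAB>gene', got {line!r}"
            )
        term, gene = parts[0].strip(), parts[1].strip()
        if first_data_row:
            first_data_row = False
            if term.lower() in _TSV_HEADER_TOKENS or gene.lower() in _TSV_HEADER_TOKENS:
                continue  # optional header row
        yield line_no, term, gene


def _iter_gaf_rows(text: str) -> Iterator[tuple[int, str, str]]:
    for line_no, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("!"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 5 or not parts[1].strip() or not parts[4].strip():
            raise AnnotationError(
                f"line {line_no}: GAF row needs >= 5 columns with gene in "
                f"column 2 and term in column 5"
            )
        # GAF 2.x: column 2 = DB Object ID (gene), column 5 = ontology term
        yield line_no, parts[4].strip(), parts[1].strip()


def load_annotations(
    table_source: str | IO[str],
    fmt: str = "tsv",
    ontology: Ontology | None = None,
) -> AnnotationMap:
    """Load a direct gene->term annotation table.

    Parameters
    ----------
    table_source
        Path or text stream.  ``fmt="tsv"`` expects two tab-separated columns
        ``term_id, gene_id`` (header optional, ``#`` comments ignored);
        ``fmt="gaf"`` reads GAF 2.x, using columns 2 (gene) and 5 (term).
    ontology
        When given, rows citing terms absent from the ontology are diverted to
        :attr:`AnnotationMap.orphans` instead of entering the gene sets; they
        are reported, not silently dropped.

    Returns
    -------
    AnnotationMap
        Direct-flavor map; duplicate rows collapse into sets.  An empty or
        fully orphaned table yields an empty map and a warning.
    """
    if fmt not in ("tsv", "gaf"):
        raise ValueError(f"unknown annotation format {fmt!r}")
    text = _as_stream(table_source).read()
    rows = _iter_tsv_rows(text) if fmt == "tsv" else _iter_gaf_rows(text)

    gene_sets: dict[str, set[str]] = {}
    orphans: list[tuple[int, str, str]] = []
    for line_no, term, gene in rows:
        if ontology is not None and term not in ontology:
            orphans.append((line_no, term, gene))
            continue
        gene_sets.setdefault(term, set()).add(gene)
    if not gene_sets:
        warnings.warn(
            "annotation table produced no usable rows", stacklevel=2
        )
    return AnnotationMap(
        gene_sets={t: frozenset(g) for t, g in gene_sets.items()},
        flavor="direct",
        orphans=tuple(orphans),
    )


# ---------------------------------------------------------------------------
# Annotation inheritance
# ---------------------------------------------------------------------------


def propagate_annotations(ont: Ontology, direct: AnnotationMap) -> AnnotationMap:
    """Propagate annotations from descendants to ancestors.

    ``inherited[t]`` is the union of ``direct[d]`` over ``t`` and every
    descendant ``d`` of ``t`` along is_a/part_of chains.  Set semantics make
    a gene reachable through several paths count once, and inherited counts
    are monotone non-decreasing from any term toward each of its ancestors.
    """
    if direct.flavor != "direct":
        raise ValueError("propagate_annotations expects a direct AnnotationMap")
    inherited: dict[str, set[str]] = {}
    # child -> parent edges: topological order lists children before parents
    for term_id in nx.topological_sort(ont.graph):
        genes = set(direct.genes(term_id))
        for child in ont.graph.predecessors(term_id):
            genes |= inherited[child]
        inherited[term_id] = genes
    return AnnotationMap(
        gene_sets={t: frozenset(g) for t, g in inherited.items()},
        flavor="inherited",
    )


def sister_sets(ont: Ontology) -> list[tuple[str, frozenset[str]]]:
    """Group terms into sister sets: the children of each shared parent.

    Returns one ``(parent_id, children)`` entry per parent with at least two
    children, sorted by parent id.  A term with k parents can belong to up to
    k sister sets.
    """
    out = []
    for parent in sorted(ont.graph.nodes):
        kids = ont.children(parent)
        if len(kids) >= 2:
            out.append((parent, frozenset(kids)))
    return out
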