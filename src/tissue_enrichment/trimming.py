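"""Dictionary compilation: trim the ontology down to statistically testable terms.

Three filters, applied in a fixed order, turn the verbose ontology into a
compact "dictionary" of terms that are well-annotated and non-redundant:

1. *Similarity filter* — sister terms (children of a common parent) whose
   inherited gene sets are nearly identical carry no independent statistical
   signal (the left/right neuron-pair situation); whole sister sets exceeding
   a similarity threshold are removed.
2. *Annotation filter* — terminal terms with fewer inherited annotations than
   a cutoff are removed, recursively up each branch until a sufficiently
   annotated term is found.  Termination is guaranteed because inherited
   counts are monotone toward the root.
3. *Ceiling filter* — a parent whose surviving children all meet the cutoff
   adds no information over testing the children directly and is removed,
   working down from the roots.

Similarity scores are always computed on the full, untrimmed ontology;
annotation and similarity trimming run first, the ceiling filter last (the
filters do not commute).  Removal only excludes a term from the testable
dictionary: inheritance is computed on the full ontology, so no annotation is
ever lost to an ancestor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

from .ontology import AnnotationMap, Ontology, propagate_annotations, sister_sets

__all__ = [
    "TrimParams",
    "SimilarityRecord",
    "Dictionary",
    "EmptyDictionaryError",
    "similarity_scores",
    "flag_redundant",
    "annotation_filter",
    "ceiling_filter",
    "build_dictionary",
    "write_dictionary",
    "read_dictionary",
]

CRITERIA = ("any", "avg")


class EmptyDictionaryError(ValueError):
    """No term survived trimming; a lower annotation cutoff is needed."""


@dataclass(frozen=True)
class TrimParams:
    """Filter configuration.

    Parameters
    ----------
    annotation_cutoff
        Minimum inherited gene count a term needs to be testable.  A term
        *passes* when its count is >= the cutoff, so cutoff 25 keeps a
        25-gene term.
    similarity_threshold
        S in (0, 1].  Sister sets are redundant when a score strictly
        exceeds S, so S = 1 disables similarity trimming (scores never
        exceed 1).
    criterion
        ``'any'``: the set is redundant if any sister's score exceeds S.
        ``'avg'``: redundant if the mean score over the set exceeds S.
    """

    annotation_cutoff: int = 33
    similarity_threshold: float = 0.95
    criterion: str = "any"

    def __post_init__(self) -> None:
        if self.annotation_cutoff < 1:
            raise ValueError("annotation_cutoff must be >= 1")
        if not 0 < self.similarity_threshold <= 1:
            raise ValueError("similarity_threshold must be in (0, 1]")
        if self.criterion not in CRITERIA:
            raise ValueError(f"criterion must be one of {CRITERIA}")


@dataclass(frozen=True)
class SimilarityRecord:
    """Similarity scores for one sister set.

    Each sister i scores ``s_i = |g_i| / |union of all sisters' gene sets|``
    on its inherited gene set g_i, so ``s_i = 1`` exactly when a sister
    carries every gene seen in the set.  ``degenerate`` marks sets whose
    union is empty (scores undefined; the set is treated as redundant, and
    would fall to the annotation filter regardless).
    """

    parent_id: str
    sister_ids: tuple[str, ...]
    scores: tuple[float, ...]
    union_size: int
    degenerate: bool = False

    def score_of(self, term_id: str) -> float:
        return self.scores[self.sister_ids.index(term_id)]


@dataclass
class Dictionary:
    """The trimmed, testable term set with inherited gene sets.

    ``total_annotations`` is N = sum of per-term gene-set sizes: the total
    number of (gene, term) pairs, so a gene annotated to j surviving terms
    contributes j.  This is the statistical background for enrichment
    testing.
    """

    entries: dict[str, frozenset[str]]
    names: dict[str, str]
    params: TrimParams
    removed_similarity: frozenset[str] = frozenset()
    removed_annotation: frozenset[str] = frozenset()
    removed_ceiling: frozenset[str] = frozenset()

    @property
    def total_annotations(self) -> int:
        return sum(len(g) for g in self.entries.values())

    @property
    def gene_universe(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.entries.values():
            out |= genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.entries


# ---------------------------------------------------------------------------
# Stage 1a: similarity scoring
# ---------------------------------------------------------------------------


def similarity_scores(
    inherited: AnnotationMap,
    sisters: Iterable[tuple[str, frozenset[str]]],
) -> list[SimilarityRecord]:
    """Score every sister set on the full, untrimmed ontology.

    For sisters with inherited gene sets g_1..g_k, sister i scores
    ``|g_i| / |g_1 ∪ ... ∪ g_k|``.  Sets with an empty union get zeroed
    scores and are flagged degenerate.
    """
    records = []
    for parent, kids in sisters:
        sister_ids = tuple(sorted(kids))
        union: set[str] = set()
        for sid in sister_ids:
            union |= inherited.genes(sid)
        if not union:
            records.append(
                SimilarityRecord(
                    parent_id=parent,
                    sister_ids=sister_ids,
                    scores=(0.0,) * len(sister_ids),
                    union_size=0,
                    degenerate=True,
                )
            )
            continue
        scores = tuple(
            len(inherited.genes(sid)) / len(union) for sid in sister_ids
        )
        records.append(
            SimilarityRecord(
                parent_id=parent,
                sister_ids=sister_ids,
                scores=scores,
                union_size=len(union),
            )
        )
    return records


def flag_redundant(
    records: Iterable[SimilarityRecord], params: TrimParams
) -> set[str]:
    """Terms to remove as members of a redundant sister set.

    Under ``'any'``, a set triggers when any sister's score strictly exceeds
    S; under ``'avg'``, when the mean score does.  A triggered set loses all
    of its sisters.  A term belonging to several sister sets is removed if
    any one of them triggers.  Degenerate (empty-union) sets always trigger.
    """
    s_max = params.similarity_threshold
    flagged: set[str] = set()
    for rec in records:
        if rec.degenerate:
            flagged.update(rec.sister_ids)
            continue
        if params.criterion == "any":
            triggered = any(s > s_max for s in rec.scores)
        else:
            triggered = sum(rec.scores) / len(rec.scores) > s_max
        if triggered:
            flagged.update(rec.sister_ids)
    return flagged


# ---------------------------------------------------------------------------
# Stage 1b: annotation (terminal-branch) filter
# ---------------------------------------------------------------------------


def annotation_filter(
    ont: Ontology,
    inherited: AnnotationMap,
    cutoff: int,
    excluded: frozenset[str] | set[str] = frozenset(),
) -> set[str]:
    """Remove under-annotated terminal terms, recursively up each branch.

    On the graph restricted to non-excluded terms, any terminal term (no
    surviving children) with fewer than ``cutoff`` inherited genes is
    removed; its removal may expose a parent as the new terminal term, which
    is then tested in turn.  The walk up a branch stops at the first term
    that passes, and passing is inclusive: count >= cutoff survives.
    """
    alive = {t for t in ont.graph.nodes if t not in excluded}
    # children remaining within the restricted graph
    n_children = {t: sum(c in alive for c in ont.children(t)) for t in alive}
    frontier = [t for t in alive if n_children[t] == 0]
    removed: set[str] = set()
    while frontier:
        term = frontier.pop()
        if inherited.count(term) >= cutoff:
            continue  # branch walk stops at the first passing term
        removed.add(term)
        alive.discard(term)
        for parent in ont.parents(term):
            if parent in alive:
                n_children[parent] -= 1
                if n_children[parent] == 0:
                    frontier.append(parent)
    return removed


# ---------------------------------------------------------------------------
# Stage 2: ceiling filter
# ---------------------------------------------------------------------------


def ceiling_filter(
    ont: Ontology,
    inherited: AnnotationMap,
    cutoff: int,
    survivors: frozenset[str] | set[str],
) -> set[str]:
    """Remove parents fully covered by well-annotated surviving children.

    Working from the roots down over ``survivors`` (the terms left after
    similarity and annotation trimming), a parent is removed when it has at
    least one surviving child and every surviving child meets the cutoff —
    testing the parent then adds nothing over testing its children.  Children
    removed by the earlier filters cannot testify: a parent whose children
    were all removed is terminal here and is kept.
    """
    removed: set[str] = set()
    for term in survivors:
        kids = [c for c in ont.children(term) if c in survivors]
        if kids and all(inherited.count(c) >= cutoff for c in kids):
            removed.add(term)
    return removed


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def build_dictionary(
    ont: Ontology, direct: AnnotationMap, params: TrimParams
) -> Dictionary:
    """Compile the testable dictionary from an ontology and direct annotations.

    Pipeline: propagate annotations over the full ontology, score all sister
    sets on the untrimmed graph, remove redundant sister sets, apply the
    annotation filter on the reduced graph, then the ceiling filter on its
    survivors.  Per-stage removal sets are recorded on the result.

    Raises
    ------
    EmptyDictionaryError
        If no term survives; lower the annotation cutoff.
    """
    inherited = propagate_annotations(ont, direct)
    records = similarity_scores(inherited, sister_sets(ont))
    flagged = flag_redundant(records, params)
    under = annotation_filter(
        ont, inherited, params.annotation_cutoff, excluded=flagged
    )
    survivors = {
        t for t in ont.graph.nodes if t not in flagged and t not in under
    }
    ceiling = ceiling_filter(ont, inherited, params.annotation_cutoff, survivors)
    survivors -= ceiling
    if not survivors:
        raise EmptyDictionaryError(
            "no term survived trimming; consider a lower annotation cutoff "
            f"(current: {params.annotation_cutoff})"
        )
    return Dictionary(
        entries={t: inherited.genes(t) for t in sorted(survivors)},
        names={t: ont.name(t) for t in sorted(survivors)},
        params=params,
        removed_similarity=frozenset(flagged),
        removed_annotation=frozenset(under),
        removed_ceiling=frozenset(ceiling),
    )


# ---------------------------------------------------------------------------
# Serialization: long-form TSV + JSON sidecar, byte-stable for fixed input
# ---------------------------------------------------------------------------


def write_dictionary(dictionary: Dictionary, out_prefix: str) -> tuple[str, str]:
    """Write ``<prefix>.dict.tsv`` (term_id, term_name, gene_id rows) and
    ``<prefix>.dict.json`` (params, per-stage removal counts, N).

    Rows are sorted by term then gene, so identical inputs produce
    byte-identical files.
    """
    tsv_path = f"{out_prefix}.dict.tsv"
    json_path = f"{out_prefix}.dict.json"
    with open(tsv_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("term_id\tterm_name\tgene_id\n")
        for term in sorted(dictionary.entries):
            name = dictionary.names.get(term, term)
            for gene in sorted(dictionary.entries[term]):
                fh.write(f"{term}\t{name}\t{gene}\n")
    meta = {
        "params": {
            "annotation_cutoff": dictionary.params.annotation_cutoff,
            "similarity_threshold": dictionary.params.similarity_threshold,
            "criterion": dictionary.params.criterion,
        },
        "n_terms": len(dictionary),
        "total_annotations": dictionary.total_annotations,
        "removed": {
            "similarity": len(dictionary.removed_similarity),
            "annotation": len(dictionary.removed_annotation),
            "ceiling": len(dictionary.removed_ceiling),
        },
    }
    with open(json_path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return tsv_path, json_path


def read_dictionary(prefix_or_tsv: str) -> Dictionary:
    """Load a dictionary written by :func:`write_dictionary`.

    Accepts the ``--out-prefix`` used at write time or the ``.dict.tsv`` path
    itself; the JSON sidecar is looked up next to the TSV.
    """
    tsv_path = (
        prefix_or_tsv
        if prefix_or_tsv.endswith(".dict.tsv")
        else f"{prefix_or_tsv}.dict.tsv"
    )
    json_path = tsv_path[: -len(".tsv")] + ".json"
    entries: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(tsv_path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("term_id\t"):
            raise ValueError(f"{tsv_path}: not a dictionary TSV")
        for line in fh:
            term, name, gene = line.rstrip("\n").split("\t")
            entries.setdefault(term, set()).add(gene)
            names[term] = name
    with open(json_path, encoding="utf-8") as fh:
        meta = json.load(fh)
    params = TrimParams(**meta["params"])
    return Dictionary(
        entries={t: frozenset(g) for t, g in entries.items()},
        names=names,
        params=params,
    )
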