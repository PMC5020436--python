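"""Hypergeometric term-enrichment testing with Benjamini-Hochberg FDR.

The model: the trimmed dictionary holds N (gene, term) annotation pairs in
total, m_i of which carry term i.  A query gene list contributes M pairs (a
gene annotated to several terms contributes one pair per term), n_i of which
carry term i.  Under the null, the query's M pairs are a uniform draw without
replacement from the N dictionary pairs, so n_i follows a hypergeometric law;
enrichment is the upper tail P(X >= n_i).

Terms with no query annotation (n_i = 0) get p = 1 and are never called
significant — the discrete hypergeometric can otherwise produce artifacts on
small lists.  BH correction runs over *all* dictionary terms so the
multiple-testing burden does not depend on query overlap.  Significance is
q < alpha, with alpha = 0.1 by default.

A gene-centric counting universe (N = distinct annotated genes, M = distinct
annotated query genes) is available via ``universe="genes"`` for comparison;
the pair-based universe is the default and is recorded in the result
metadata.  Depletion testing (lower tail) is an off-by-default extension.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .trimming import Dictionary

__all__ = [
    "QueryProfile",
    "EnrichmentResult",
    "hypergeom_tail",
    "bh_stepup",
    "build_query_profile",
    "test_list",
    "results_to_frame",
]

DEFAULT_ALPHA = 0.1

RESULT_COLUMNS = [
    "term_id",
    "term_name",
    "observed",
    "expected",
    "fold_change",
    "p_value",
    "q_value",
    "significant",
]


@dataclass(frozen=True)
class QueryProfile:
    """The query gene list as seen by the dictionary.

    ``genes`` are the query genes found in at least one dictionary term;
    ``total`` is M, the number of (gene, term) pairs they contribute; and
    ``observed[t]`` is n_t, the number of query genes annotated to term t
    (absent keys mean 0).  M equals the sum of the observed counts.
    """

    genes: frozenset[str]
    total: int
    observed: dict[str, int]


@dataclass(frozen=True)
class EnrichmentResult:
    """One dictionary term's enrichment outcome for a query list."""

    term_id: str
    term_name: str
    observed: int
    dictionary_count: int
    expected: float
    fold_change: float
    p_value: float
    q_value: float
    significant: bool


def hypergeom_tail(n_i: int, m_i: int, M: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= n_i).

    X counts marked items when drawing M items without replacement from a
    population of N containing m_i marked items.  Computed with scipy's
    survival function (numerically safe in the far tail).

    Raises
    ------
    ValueError
        If the arguments do not describe a valid draw; arguments are never
        silently clipped.
    """
    if not (0 <= m_i <= N and 0 <= M <= N):
        raise ValueError(
            f"invalid population: m_i={m_i}, M={M} must lie in [0, N={N}]"
        )
    if not 0 <= n_i <= min(m_i, M):
        raise ValueError(
            f"observed count n_i={n_i} outside [0, min(m_i={m_i}, M={M})]"
        )
    if n_i == 0:
        return 1.0
    return float(hypergeom.sf(n_i - 1, N, m_i, M))


def bh_stepup(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the order of the input.

    For sorted p-values p_(1) <= ... <= p_(m), the q-value of p_(i) is
    ``min over j >= i of m * p_(j) / j``, capped at 1; ties share a q.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_query_profile(genes: Iterable[str], dictionary: Dictionary) -> QueryProfile:
    """Project a canonicalized query gene set onto the dictionary."""
    query = frozenset(genes)
    observed: dict[str, int] = {}
    used: set[str] = set()
    for term, term_genes in dictionary.entries.items():
        hits = query & term_genes
        if hits:
            observed[term] = len(hits)
            used |= hits
    return QueryProfile(
        genes=frozenset(used),
        total=sum(observed.values()),
        observed=observed,
    )


def _counts(
    query: frozenset[str], dictionary: Dictionary, universe: str
) -> tuple[int, int, dict[str, int], dict[str, int]]:
    """(N, M, m_i per term, n_i per term) for the chosen counting universe."""
    m = {t: len(g) for t, g in dictionary.entries.items()}
    n = {t: len(query & g) for t, g in dictionary.entries.items()}
    if universe == "pairs":
        N = sum(m.values())
        M = sum(n.values())
    elif universe == "genes":
        N = len(dictionary.gene_universe)
        M = len(query & dictionary.gene_universe)
    else:
        raise ValueError("universe must be 'pairs' or 'genes'")
    return N, M, m, n


def test_list(
    genes: Iterable[str],
    dictionary: Dictionary,
    alpha: float = DEFAULT_ALPHA,
    universe: str = "pairs",
    depletion: bool = False,
) -> list[EnrichmentResult]:
    """Test a canonicalized gene list for term enrichment.

    Parameters
    ----------
    genes
        Canonical gene ids (see :mod:`tissue_enrichment.idmap` for name
        mapping).
    dictionary
        The trimmed, testable dictionary (the statistical background).
    alpha
        Significance threshold on the q-value (strict: significant means
        q < alpha), default 0.1.
    universe
        ``"pairs"`` (default) counts (gene, term) annotation pairs, so one
        gene can contribute to several terms; ``"genes"`` counts distinct
        genes.
    depletion
        If true, test the lower tail P(X <= n_i) instead (extension; the
        default and standard mode is enrichment).

    Returns
    -------
    list of EnrichmentResult
        One row per dictionary term, sorted by ascending q-value, then
        descending fold change, then term id.  Empty (with a warning) when
        no query gene maps into the dictionary.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if len(dictionary) == 0:
        raise ValueError("dictionary is empty")
    query = frozenset(genes)
    N, M, m, n = _counts(query, dictionary, universe)
    if M == 0:
        warnings.warn(
            "no query gene maps into the dictionary; empty result",
            stacklevel=2,
        )
        return []

    terms = sorted(dictionary.entries)
    p_values = np.ones(len(terms))
    for i, t in enumerate(terms):
        if depletion:
            # lower tail; n = 0 is the informative case here
            p_values[i] = float(hypergeom.cdf(n[t], N, m[t], M))
        elif n[t] >= 1:
            p_values[i] = hypergeom_tail(n[t], m[t], M, N)
        # else p = 1: never significant without annotations in the list
    q_values = bh_stepup(p_values)

    results = []
    for i, t in enumerate(terms):
        expected = M * m[t] / N
        fold = n[t] / expected if expected > 0 else 0.0
        results.append(
            EnrichmentResult(
                term_id=t,
                term_name=dictionary.names.get(t, t),
                observed=n[t],
                dictionary_count=m[t],
                expected=expected,
                fold_change=fold,
                p_value=float(p_values[i]),
                q_value=float(q_values[i]),
                significant=bool(
                    q_values[i] < alpha and (depletion or n[t] >= 1)
                ),
            )
        )
    results.sort(key=lambda r: (r.q_value, -r.fold_change, r.term_id))
    return results


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Results as a DataFrame in canonical order (significant rows first)."""
    frame = pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "term_name": r.term_name,
                "observed": r.observed,
                "expected": r.expected,
                "fold_change": r.fold_change,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "significant": r.significant,
            }
            for r in results
        ],
        columns=RESULT_COLUMNS,
    )
    return frame
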