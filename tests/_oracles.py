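"""Independent brute-force oracles used to check the implementation.

Everything here is written from first principles on plain lists/sets/dicts —
no networkx, no scipy special functions, no statsmodels — so the checks stay
independent of the code paths they verify.
"""

from __future__ import annotations

from itertools import combinations
from math import comb


def reachable_descendants(term_id, child_to_parents):
    """All strict descendants of ``term_id`` by repeated edge expansion."""
    parent_of = {}  # parent -> set of children
    for child, parents in child_to_parents.items():
        for parent in parents:
            parent_of.setdefault(parent, set()).add(child)
    out, frontier = set(), {term_id}
    while frontier:
        nxt = set()
        for node in frontier:
            for child in parent_of.get(node, ()):
                if child not in out:
                    out.add(child)
                    nxt.add(child)
        frontier = nxt
    return out


def inherited_oracle(child_to_parents, direct):
    """inherited[t] = union of direct over {t} plus all descendants of t."""
    out = {}
    for term in child_to_parents:
        genes = set(direct.get(term, ()))
        for desc in reachable_descendants(term, child_to_parents):
            genes |= set(direct.get(desc, ()))
        out[term] = genes
    return out


def annotation_filter_oracle(child_to_parents, counts, cutoff, excluded=()):
    """Fixed point of: delete any terminal node with count < cutoff."""
    alive = set(child_to_parents) - set(excluded)
    changed = True
    while changed:
        changed = False
        for node in sorted(alive):
            has_child = any(
                node in child_to_parents[c] and c in alive
                for c in child_to_parents
            )
            if not has_child and counts.get(node, 0) < cutoff:
                alive.discard(node)
                changed = True
    return (set(child_to_parents) - set(excluded)) - alive


def ceiling_filter_oracle(child_to_parents, counts, cutoff, survivors):
    """Parents whose surviving children (>= 1 of them) all meet the cutoff."""
    removed = set()
    for node in survivors:
        kids = [
            c for c in child_to_parents
            if node in child_to_parents[c] and c in survivors
        ]
        if kids and all(counts.get(c, 0) >= cutoff for c in kids):
            removed.add(node)
    return removed


def similarity_flag_oracle(parent_children, inherited_sets, threshold, criterion):
    """Re-derive redundant-sister flags directly from the gene sets."""
    flagged = set()
    for parent, kids in parent_children:
        union = set()
        for kid in kids:
            union |= set(inherited_sets.get(kid, ()))
        if not union:
            flagged |= set(kids)
            continue
        scores = [len(set(inherited_sets.get(k, ()))) / len(union) for k in kids]
        if criterion == "any":
            hit = any(s > threshold for s in scores)
        else:
            hit = sum(scores) / len(scores) > threshold
        if hit:
            flagged |= set(kids)
    return flagged


def hypergeom_pmf_by_enumeration(N, m, M):
    """P(X = k) by enumerating every size-M draw from an N-item urn.

    The urn holds m marked items (indices < m).  Returns a list indexed by k.
    """
    counts = [0] * (min(m, M) + 1)
    total = 0
    for draw in combinations(range(N), M):
        k = sum(1 for item in draw if item < m)
        counts[k] += 1
        total += 1
    return [c / total for c in counts]


def hypergeom_tail_closed_form(n, m, M, N):
    """Upper tail from the closed-form PMF with exact integer binomials."""
    denom = comb(N, M)
    return sum(
        comb(m, k) * comb(N - m, M - k) for k in range(n, min(m, M) + 1)
    ) / denom


def bh_stepup_naive(p_values):
    """Quadratic-time Benjamini-Hochberg step-up, mapped to input order."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    for rank, idx in enumerate(order, start=1):
        best = min(
            m * p_values[order[j]] / (j + 1) for j in range(rank - 1, m)
        )
        q[idx] = min(1.0, best)
    return q
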