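# Methods

## The model

The package treats an anatomy ontology as a rooted directed acyclic graph
whose `is_a` and `part_of` edges imply annotation inheritance: a gene
annotated to a term is implicitly annotated to every ancestor, so inherited
annotation counts are monotone non-decreasing toward the root. The two
relation types are handled identically — for inheritance and for deciding
sisterhood — because their biological reading ("is a kind of", "is part
of") licenses the same upward propagation of expression evidence. Other
relation types (e.g. `develops_from`) are ignored. Multi-parent terms and
multi-root ontologies are supported as-is; no artificial super-root is
added. Obsolete terms are parsed and retained for bookkeeping but excluded
from the edge relation and from propagation.

Enrichment testing uses the standard hypergeometric urn: the dictionary's
N (gene, term) pairs are the population, the m_i pairs of term i are the
marked items, the query's M pairs are the draw, and the p-value is the
upper tail P(X ≥ n_i), computed with scipy's survival function (log-space
internally, stable in the far tail). Benjamini–Hochberg step-up q-values
are computed over all dictionary terms via statsmodels.

## Pipeline order and tie-breaks

The three trimming filters do not commute. The fixed order is: similarity
scores computed on the *untrimmed* graph, similarity removal applied, the
annotation filter run on the reduced graph, and the ceiling filter last,
over the survivors of the first two stages. Choices at the edges:

- **Inclusive cutoff.** A term passes the annotation threshold when its
  inherited count is ≥ the cutoff, so cutoff 25 keeps a 25-gene term. The
  strict variant is a one-character change in `annotation_filter` /
  `ceiling_filter` but is not exposed.
- **Strict similarity inequality.** A sister set triggers only when a
  score (or the mean) strictly exceeds S. Since scores cannot exceed 1,
  S = 1 disables similarity trimming entirely.
- **Empty-union sister sets** (all sisters unannotated) have undefined
  scores; they are flagged redundant outright. The annotation filter would
  remove them anyway, so this only affects stage attribution.
- **Ceiling-filter scope.** The "all daughters pass" condition is
  evaluated over surviving children only; removed children cannot testify.
  A parent whose children were all removed is terminal at that stage and
  is kept if it passed the annotation filter. Because the condition
  depends only on the stage's input survivor set, the filter is
  order-independent and computed in one pass.
- **Removal never destroys information**: inheritance is computed on the
  full ontology before any filter, so a removed child's genes remain
  counted in every ancestor.

## Enrichment choices

- **Pair universe by default.** N and M count (gene, term) pairs, so one
  gene contributes to every term that carries it. A gene-centric universe
  (N = distinct annotated genes, M = distinct annotated query genes) is
  available via `universe="genes"` for comparison.
- **Zero-annotation guard.** Terms with n_i = 0 receive p = 1 and can
  never be significant; the discrete test can otherwise behave erratically
  on small lists.
- **BH over all terms.** The correction denominator is the full dictionary
  (n_i = 0 terms enter at p = 1), so the multiple-testing burden does not
  depend on how much of the dictionary the query happens to touch.
- **α = 0.1** by default, strict comparison (q < α), tunable from the CLI
  and API.
- **Canonical sort**: ascending q, then descending fold change, then term
  id — the term-id tie-break makes output order fully deterministic.
- Depletion (lower-tail) testing exists behind an off-by-default flag as a
  labelled extension; there the n_i = 0 guard is inverted, since absence
  is the signal.

## Synthetic data

The fixture generator emulates the structural features the filters assume,
not any real ontology's statistics:

- **Topology**: node i draws its parent(s) uniformly from nodes with index
  < i (second parent with probability 0.1, at most 5 children per node),
  so acyclicity holds by construction. Default 60 core terms.
- **Annotations**: only leaves are directly annotated; counts are discrete
  uniform on [0, 60] over a 500-gene pool, which yields both well-annotated
  branches and the sparse leaves the annotation filter exists for, with
  inherited counts monotone toward the root.
- **Planted redundancy**: two sister pairs whose gene sets differ by one
  gene out of 31 (Jaccard ≈ 0.97), attached under dedicated parents — the
  left/right neuron-pair analogue the similarity filter targets.
- **Planted enrichment**: one 40-gene leaf attached as the only child of a
  dedicated parent (so it joins no sister set and, as a leaf, is immune to
  the ceiling filter); the query takes 80 % of its genes plus 5 random
  background genes. Null-mode queries are 30 uniform draws from the pool.

What passing tests on these fixtures does *not* show: real curation biases
(e.g. under-reported germline expression), annotation sizes spanning four
orders of magnitude, or term counts in the thousands — the generator's
`n_terms` can be raised but defaults are desk-scale. The similarity metric
|g_i|/|union| deliberately flags *unbalanced* sister sets too (one sister
dominating the union scores near 1); on random backgrounds this legitimately
fires beyond the planted pairs, which is why the universal test property is
"planted pairs ⊆ flagged", with exact equality asserted on balanced seeds.

## Problem sizes and verification

Unit and property tests check each stage against independent brute-force
oracles (transitive-closure inheritance, fixed-point deletion filters,
exhaustive-enumeration hypergeometric tails for populations ≤ 12, a
quadratic-time BH step-up) across 200 generated DAGs of ≤ ~70 nodes.
Statistical behaviour is measured over 200 replicates each for planted
recovery (≥ 95 % required) and null false-positive rate (must stay within
binomial noise of the 0.1 FDR target); both finish in seconds at these
sizes. All file outputs (dictionary TSV + JSON sidecar, results TSV, SVG
chart) are byte-deterministic for fixed inputs: rows are emitted in sorted
order and the chart uses a fixed palette, fixed hash salt and no embedded
timestamps.

## Known limitations

- Only `is_a`/`part_of` edges are honoured; OWL ontologies and other
  relation types are out of scope.
- The enrichment model assumes exchangeable annotation pairs; correlated
  annotations along a branch are mitigated by trimming, not modelled.
- No fuzzy gene-name matching: canonicalization is exact (case-insensitive)
  against a user-supplied alias table.
- False-positive/negative rates on real curated data cannot be derived
  from synthetic fixtures; treat enrichment output as hypothesis-forming.
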