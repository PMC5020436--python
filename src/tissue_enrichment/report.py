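"""Reporting: results table serialization and the top-15 enrichment bar chart.

The chart mirrors the canonical result order — ascending q-value, then
descending fold change, ties broken by term id — and shows at most the 15
most significant terms as horizontal bars of enrichment fold change, labelled
"name (term_id)".  Bar colors are decorative only and are drawn from a fixed
palette so that SVG output is byte-stable run to run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt

from .enrichment import EnrichmentResult, results_to_frame

__all__ = ["ChartSpec", "select_top", "render_chart", "write_results"]

logger = logging.getLogger("tissue_enrichment")

DEFAULT_TOP_K = 15

# fixed decorative palette (matplotlib 'tab10' hexes); color conveys nothing
_PALETTE = [
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
]


@dataclass(frozen=True)
class ChartSpec:
    """Rows destined for the bar chart, in canonical order."""

    rows: tuple[EnrichmentResult, ...]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(f"{r.term_name} ({r.term_id})" for r in self.rows)

    @property
    def fold_changes(self) -> tuple[float, ...]:
        return tuple(r.fold_change for r in self.rows)

    def __len__(self) -> int:
        return len(self.rows)


def select_top(
    results: Sequence[EnrichmentResult], k: int = DEFAULT_TOP_K
) -> ChartSpec:
    """Take the first ``min(k, #significant)`` rows of canonically sorted results.

    Results are assumed already sorted by (q ascending, fold change
    descending, term id); only significant rows are charted.  With no
    significant rows the spec is empty and the chart is skipped.
    """
    significant = [r for r in results if r.significant]
    if not significant:
        logger.info("no significant terms; chart skipped")
    return ChartSpec(rows=tuple(significant[:k]))


def render_chart(spec: ChartSpec, path: str) -> str:
    """Render the horizontal fold-change bar chart to SVG or PNG.

    The most significant term is drawn topmost.  Output is deterministic:
    fixed palette, fixed hash salt, no embedded timestamps, so rendering the
    same spec twice yields identical SVG text.
    """
    if len(spec) == 0:
        raise ValueError("cannot render an empty chart")
    with matplotlib.rc_context({"svg.hashsalt": "tissue-enrichment"}):
        height = max(1.8, 0.42 * len(spec) + 1.0)
        fig, ax = plt.subplots(figsize=(7.5, height))
        positions = range(len(spec))
        colors = [_PALETTE[i % len(_PALETTE)] for i in positions]
        ax.barh(list(positions), spec.fold_changes, color=colors)
        ax.set_yticks(list(positions))
        ax.set_yticklabels(spec.labels, fontsize=8)
        ax.invert_yaxis()  # best term on top
        ax.set_xlabel("enrichment fold change")
        fig.tight_layout()
        if path.lower().endswith(".svg"):
            fig.savefig(path, metadata={"Date": None})  # no timestamp
        else:
            fig.savefig(path)
        plt.close(fig)
    return path


def write_results(results: Sequence[EnrichmentResult], path: str) -> str:
    """Write the full results table as TSV, significant rows first."""
    frame = results_to_frame(results)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g",
                 lineterminator="\n")
    return path
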