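"""The four visualization modes, each emitted as figure + exact table.

Every export writes ``<out>.tsv`` (the exact data behind the figure, enough
to reconstruct it) plus ``<out>.png`` and ``<out>.svg``.  Edge widths on the
network map a rescaled score in [1, 10] linearly onto a configurable pixel
range; compartment colors default to the stroma/innate/adaptive/epithelium
scheme.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd

from .scoring import ScoreMatrix
from .stats import ComparisonTable

logger = logging.getLogger(__name__)

COMPARTMENT_COLORS = {
    "stroma": "#4daf4a",      # green
    "innate": "#ff7f00",      # orange
    "adaptive": "#377eb8",    # blue
    "epithelium": "#f781bf",  # pink
    "central": "#999999",     # gray
    "other": "#cccccc",
}


def edge_width(score: float, w_min: float = 1.0, w_max: float = 8.0) -> float:
    """Map a rescaled score in [1, 10] linearly onto [w_min, w_max]."""
    return w_min + (score - 1.0) / 9.0 * (w_max - w_min)


def _save(fig, out_path: Path) -> None:
    fig.savefig(out_path.with_suffix(".png"), dpi=150, bbox_inches="tight")
    fig.savefig(out_path.with_suffix(".svg"), bbox_inches="tight")
    plt.close(fig)


def export_network(
    sm: ScoreMatrix,
    node_categories: Mapping[str, str],
    out_path: str | Path,
    seed: int = 0,
    w_min: float = 1.0,
    w_max: float = 8.0,
    integer_labels: bool = True,
) -> pd.DataFrame:
    """Directed connectivity map; edge width proportional to rescaled score.

    Requires the rescaled view.  Returns (and writes) the edge table with
    columns source, target, raw_score, rescaled_score, width.
    """
    if sm.rescaled is None:
        raise ValueError("score matrix has no rescaled view; call rescale_scores")
    out_path = Path(out_path)

    rows = []
    for cond in sm.rescaled.index:
        for partner in sm.rescaled.columns:
            rescaled = float(sm.rescaled.loc[cond, partner])
            raw = float(sm.raw.loc[cond, partner])
            src, dst = (cond, partner) if sm.direction == "out" else (partner, cond)
            rows.append((src, dst, raw, rescaled, edge_width(rescaled, w_min, w_max)))
    table = pd.DataFrame(
        rows, columns=["source", "target", "raw_score", "rescaled_score", "width"]
    )
    table.to_csv(out_path.with_suffix(".tsv"), sep="\t", index=False)

    graph = nx.DiGraph()
    centrals = set(sm.rescaled.index)
    for node in set(table["source"]) | set(table["target"]):
        category = node_categories.get(node)
        if category is None:
            category = "central" if node in centrals else "other"
            if node not in centrals:
                logger.warning("node %r has no compartment; using 'other'", node)
        graph.add_node(node, category=category)
    for _, row in table.iterrows():
        graph.add_edge(row["source"], row["target"], width=row["width"],
                       score=row["rescaled_score"])

    pos = nx.spring_layout(graph, seed=seed)
    fig, ax = plt.subplots(figsize=(7, 6))
    colors = [
        COMPARTMENT_COLORS.get(graph.nodes[n]["category"], COMPARTMENT_COLORS["other"])
        for n in graph.nodes
    ]
    nx.draw_networkx_nodes(graph, pos, node_color=colors, node_size=900, ax=ax)
    nx.draw_networkx_labels(graph, pos, font_size=8, ax=ax)
    widths = [graph.edges[e]["width"] for e in graph.edges]
    nx.draw_networkx_edges(graph, pos, width=widths, ax=ax,
                           arrows=True, connectionstyle="arc3,rad=0.1")
    labels = {
        e: (f"{graph.edges[e]['score']:.0f}" if integer_labels
            else f"{graph.edges[e]['score']:.2f}")
        for e in graph.edges
    }
    nx.draw_networkx_edge_labels(graph, pos, edge_labels=labels, font_size=7, ax=ax)
    ax.set_axis_off()
    _save(fig, out_path)
    return table


def export_barplot(
    contributions: pd.DataFrame,
    out_path: str | Path,
    comparisons: ComparisonTable | None = None,
) -> pd.DataFrame:
    """Stacked barplot: family contributions (rows) per column.

    Stacked segments of a column sum to that column's global score.  When a
    comparison table is supplied, columns involved in at least one
    significant pair are starred and the adjusted p-values are written to
    ``<out>_pvalues.tsv``.
    """
    out_path = Path(out_path)
    contributions.to_csv(out_path.with_suffix(".tsv"), sep="\t")

    fig, ax = plt.subplots(figsize=(1.2 + contributions.shape[1], 5))
    bottom = np.zeros(contributions.shape[1])
    for family in contributions.index:
        vals = contributions.loc[family].to_numpy(dtype=float)
        ax.bar(contributions.columns, vals, bottom=bottom, label=str(family))
        bottom += vals
    starred = set()
    if comparisons is not None:
        comparisons.adjusted.to_csv(
            out_path.with_name(out_path.stem + "_pvalues.tsv"), sep="\t"
        )
        for res in comparisons.results:
            if res.significant:
                starred |= {res.label_a, res.label_b}
        for i, col in enumerate(contributions.columns):
            if col in starred:
                ax.annotate("*", (i, bottom[i]), ha="center", fontsize=14)
    ax.set_ylabel("communication score")
    ax.legend(fontsize=7, loc="upper right")
    _save(fig, out_path)
    return contributions


def export_balloon(
    breakdowns: pd.DataFrame,
    out_path: str | Path,
    cutoff: float = 10.0,
    percent: bool = False,
) -> pd.DataFrame:
    """Balloon plot of per-interaction scores, filtered by contribution.

    An interaction (row) is shown if its score reaches ``cutoff`` in at
    least one column; the other columns are shown at their actual values.
    With ``cutoff=0`` every interaction that is nonzero somewhere is shown.
    ``percent`` switches balloon sizes to percent of the column total.
    """
    out_path = Path(out_path)
    data = breakdowns.fillna(0.0)
    if percent:
        totals = data.sum(axis=0)
        data = 100.0 * data / totals.replace(0, np.nan)
        data = data.fillna(0.0)
    keep = (data >= cutoff).any(axis=1) if cutoff > 0 else (data > 0).any(axis=1)
    shown = data[keep]
    shown.to_csv(out_path.with_suffix(".tsv"), sep="\t")

    fig, ax = plt.subplots(
        figsize=(1.5 + shown.shape[1], 0.6 + 0.25 * max(1, shown.shape[0]))
    )
    if shown.size:
        max_val = float(shown.to_numpy().max()) or 1.0
        for yi, interaction in enumerate(shown.index):
            for xi, col in enumerate(shown.columns):
                v = float(shown.loc[interaction, col])
                if v > 0:
                    ax.scatter(xi, yi, s=400.0 * v / max_val, c="#d73027",
                               alpha=0.8, edgecolors="none")
        ax.set_xticks(range(shown.shape[1]), [str(c) for c in shown.columns],
                      rotation=45, ha="right")
        ax.set_yticks(range(shown.shape[0]), [str(i) for i in shown.index],
                      fontsize=7)
        ax.invert_yaxis()
    else:
        ax.text(0.5, 0.5, "no interaction passes the cutoff",
                ha="center", va="center")
        ax.set_axis_off()
    _save(fig, out_path)
    return shown


def export_pvalue_heatmap(
    comparisons: ComparisonTable, out_path: str | Path
) -> pd.DataFrame:
    """Symmetric heatmap of BH-adjusted p-values; diagonal left blank."""
    if len(comparisons.labels) < 2:
        raise ValueError("nothing to compare: need at least two groups")
    out_path = Path(out_path)
    adjusted = comparisons.adjusted
    adjusted.to_csv(out_path.with_suffix(".tsv"), sep="\t")

    fig, ax = plt.subplots(figsize=(1.5 + adjusted.shape[1], 1.0 + adjusted.shape[0]))
    masked = np.ma.masked_invalid(adjusted.to_numpy(dtype=float))
    im = ax.imshow(masked, cmap="viridis_r", vmin=0.0, vmax=1.0)
    ax.set_xticks(range(len(adjusted.columns)), adjusted.columns,
                  rotation=45, ha="right")
    ax.set_yticks(range(len(adjusted.index)), adjusted.index)
    for i in range(adjusted.shape[0]):
        for j in range(adjusted.shape[1]):
            if i != j:
                ax.text(j, i, f"{adjusted.iloc[i, j]:.3f}", ha="center",
                        va="center", fontsize=7, color="white")
    fig.colorbar(im, ax=ax, label="adjusted p")
    _save(fig, out_path)
    return adjusted
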