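"""Catalogue assembly and clustered heatmap overviews.

Everything upstream is keyed on gene ids, so a comprehensive catalogue —
called genes, their matched aging terms and diseases with publication
counts, pathway provenance, and external annotations — is a join on
gene_id.  The heatmap overview hierarchically clusters the rows and columns
of a Dice score matrix (average linkage on Euclidean distance by default)
and renders the reordered grid; rendering never alters the scores, and the
reordered matrix is exported alongside the image so the display order is
auditable.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .scoring import DiceMatrix


def _format_evidence(evidence: Mapping[str, int]) -> str:
    return ";".join(f"{term}:{count}" for term, count in sorted(evidence.items()))


def build_catalogue(
    called_genes: Mapping[str, Mapping[str, int]],
    symbols: Mapping[str, str] | None = None,
    disease_evidence: Mapping[str, Mapping[str, int]] | None = None,
    expansions: Mapping[str, set] | None = None,
    annotations: Mapping[str, Iterable[str]] | None = None,
) -> pd.DataFrame:
    """One catalogue row per gene, joined on gene_id.

    ``called_genes`` maps gene -> {aging term: doc_count}; genes present
    only in ``expansions`` (pathway-derived) get rows with empty term
    evidence.  Rows are ordered by descending total doc_count, ties broken
    by gene_id.
    """
    disease_evidence = disease_evidence or {}
    expansions = expansions or {}
    annotations = annotations or {}

    gene_ids = set(called_genes) | set(expansions)
    annotation_sets = {label: set(genes) for label, genes in annotations.items()}

    rows = []
    for gene_id in gene_ids:
        term_ev = called_genes.get(gene_id, {})
        if any(count < 1 for count in term_ev.values()):
            raise ValueError(f"gene {gene_id}: evidence with doc_count < 1")
        row = {
            "gene_id": gene_id,
            "primary_symbol": (symbols or {}).get(gene_id, ""),
            "aging_terms": _format_evidence(term_ev),
            "n_aging_terms": len(term_ev),
            "total_doc_count": int(sum(term_ev.values())),
            "diseases": _format_evidence(disease_evidence.get(gene_id, {})),
            "pathway_provenance": ";".join(
                f"{p}<-{s}" for p, s in sorted(expansions.get(gene_id, set()))
            ),
        }
        for label, members in annotation_sets.items():
            row[label] = gene_id in members
        rows.append(row)

    catalogue = pd.DataFrame(rows)
    if catalogue.empty:
        return catalogue
    if catalogue["gene_id"].duplicated().any():
        raise ValueError("duplicate gene rows in catalogue input")
    return catalogue.sort_values(
        ["total_doc_count", "gene_id"], ascending=[False, True]
    ).reset_index(drop=True)


def select_top_genes(
    evidence: Mapping[str, Mapping[str, int]],
    k: int,
    terms: Iterable[str] | None = None,
) -> list[str]:
    """Top-k genes by summed doc_count over the selected term columns.

    With ``terms`` omitted every evidenced term counts.  Ties are broken by
    ascending gene_id so the selection is deterministic.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    wanted = set(terms) if terms is not None else None

    def total(gene: str) -> int:
        ev = evidence[gene]
        return sum(c for t, c in ev.items() if wanted is None or t in wanted)

    ranked = sorted(evidence, key=lambda g: (-total(g), g))
    return ranked[:k]


def cluster_and_render(
    matrix: DiceMatrix,
    *,
    method: str = "average",
    metric: str = "euclidean",
    drop_zero_rows: bool = True,
    out_png=None,
    out_svg=None,
    out_tsv=None,
    cmap: str = "YlOrRd",
) -> tuple[list[str], list[str], DiceMatrix]:
    """Cluster rows and columns of a score matrix and render the heatmap.

    Returns (row order, column order, reordered matrix); the reordered
    matrix holds exactly the input scores, permuted.  Genes with all-zero
    rows are excluded from the display by default — they co-occur with none
    of the selected terms and would cluster as an uninformative block.
    Deterministic for fixed inputs and parameters.
    """
    if drop_zero_rows:
        matrix = matrix.drop_zero_rows()
    if not matrix.row_ids or not matrix.col_ids:
        raise ValueError("matrix is empty after zero-row removal")
    if not np.isfinite(matrix.scores).all():
        raise ValueError("matrix contains non-finite scores")

    def leaf_order(data: np.ndarray) -> np.ndarray:
        if data.shape[0] < 2:
            return np.arange(data.shape[0])
        return leaves_list(linkage(pdist(data, metric=metric), method=method))

    row_perm = leaf_order(matrix.scores)
    col_perm = leaf_order(matrix.scores.T)

    ordered = DiceMatrix(
        row_ids=[matrix.row_ids[i] for i in row_perm],
        col_ids=[matrix.col_ids[j] for j in col_perm],
        scores=matrix.scores[np.ix_(row_perm, col_perm)],
    )

    if out_tsv is not None:
        ordered.to_tsv(out_tsv)
    if out_png is not None or out_svg is not None:
        _render(ordered, cmap, out_png, out_svg)
    return ordered.row_ids, ordered.col_ids, ordered


def _render(matrix: DiceMatrix, cmap: str, out_png, out_svg) -> None:
    n_rows, n_cols = matrix.scores.shape
    height = min(20.0, max(3.0, 0.03 * n_rows + 2.0))
    width = max(4.0, 0.5 * n_cols + 2.0)
    fig, ax = plt.subplots(figsize=(width, height))
    image = ax.imshow(
        matrix.scores, aspect="auto", interpolation="nearest", cmap=cmap,
        vmin=0.0, vmax=max(1e-9, matrix.scores.max()),
    )
    ax.set_xticks(range(n_cols))
    ax.set_xticklabels(matrix.col_ids, rotation=90, fontsize=7)
    if n_rows <= 60:
        ax.set_yticks(range(n_rows))
        ax.set_yticklabels(matrix.row_ids, fontsize=6)
    else:
        ax.set_yticks([])
    ax.set_ylabel(f"{n_rows} genes")
    fig.colorbar(image, ax=ax, label="Dice score", shrink=0.6)
    fig.tight_layout()
    if out_png is not None:
        fig.savefig(out_png, dpi=150)
    if out_svg is not None:
        fig.savefig(out_svg)
    plt.close(fig)
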