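"""Dice association scoring between genes and terms.

The association strength of two words x and y over a document collection is
the Dice coefficient

    Dice(x, y) = 2 * f(x, y) / (f(x) + f(y))

with f(x), f(y) the numbers of documents containing each word anywhere in
the abstract and f(x, y) the number containing both.  The score lies in
[0, 1]; 1 means the document sets coincide (perfect overlap).  A variant
with the product f(x)*f(y) in the denominator is available behind a flag
for auditing, but it is not a normalized coefficient (it exceeds 1 for
small overlapping sets) and is never the default.

``dice_matrix`` assembles the gene x term score grid that the heatmap
overview renders.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FrequencyTriple:
    """Document frequencies of x, of y, and of their joint occurrence."""

    f_x: int
    f_y: int
    f_xy: int

    def __post_init__(self) -> None:
        if min(self.f_x, self.f_y, self.f_xy) < 0:
            raise ValueError("frequencies must be non-negative")
        if self.f_xy > min(self.f_x, self.f_y):
            raise ValueError(
                f"joint frequency {self.f_xy} exceeds a marginal "
                f"({self.f_x}, {self.f_y})"
            )


def dice(f_x: int, f_y: int, f_xy: int, *, denominator: str = "sum") -> float:
    """Dice score of a frequency triple; 0.0 when both marginals are zero."""
    FrequencyTriple(f_x, f_y, f_xy)  # validates the invariants
    if f_xy == 0:
        return 0.0
    if denominator == "sum":
        return 2.0 * f_xy / (f_x + f_y)
    if denominator == "product":
        return 2.0 * f_xy / (f_x * f_y)
    raise ValueError(f"unknown denominator form: {denominator!r}")


@dataclass
class DiceMatrix:
    """Dense gene x term association grid with ordered id axes."""

    row_ids: list[str]
    col_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("score grid shape does not match id lists")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.row_ids, columns=self.col_ids)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path) -> "DiceMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            row_ids=[str(i) for i in frame.index],
            col_ids=[str(c) for c in frame.columns],
            scores=frame.to_numpy(dtype=float),
        )

    def zero_rows(self) -> list[str]:
        """Genes whose scores vanish for every column (droppable for display)."""
        mask = ~self.scores.any(axis=1)
        return [g for g, z in zip(self.row_ids, mask) if z]

    def drop_zero_rows(self) -> "DiceMatrix":
        mask = self.scores.any(axis=1)
        return DiceMatrix(
            row_ids=[g for g, keep in zip(self.row_ids, mask) if keep],
            col_ids=list(self.col_ids),
            scores=self.scores[mask],
        )


def _doc_sets(occurrences: pd.DataFrame) -> dict[str, frozenset[str]]:
    if occurrences.empty:
        return {}
    grouped = occurrences.groupby("entity_id")["doc_id"].agg(frozenset)
    return grouped.to_dict()


def _sentence_sets(occurrences: pd.DataFrame) -> dict[str, frozenset]:
    if occurrences.empty:
        return {}
    pairs = occurrences.assign(
        key=list(zip(occurrences["doc_id"], occurrences["sentence_index"]))
    )
    return pairs.groupby("entity_id")["key"].agg(frozenset).to_dict()


def dice_matrix(
    gene_occurrences: pd.DataFrame,
    term_occurrences: pd.DataFrame,
    genes: list[str],
    terms: list[str],
    *,
    scope: str = "abstract",
    denominator: str = "sum",
) -> DiceMatrix:
    """Score every (gene, term) cell from occurrence tables.

    Frequencies are distinct-document counts at abstract scope by default;
    at sentence scope the units are (document, sentence) pairs and the
    joint frequency counts distinct documents with a shared sentence.
    Ids absent from the occurrence universe score 0 with a warning.
    """
    if scope == "abstract":
        gene_sets = _doc_sets(gene_occurrences)
        term_sets = _doc_sets(term_occurrences)
        joint = lambda g, t: len(
            {d for d in gene_sets[g] if d in term_sets[t]}
        )
        size = len
    elif scope == "sentence":
        gene_sets = _sentence_sets(gene_occurrences)
        term_sets = _sentence_sets(term_occurrences)
        joint = lambda g, t: len(
            {doc for (doc, sent) in gene_sets[g] if (doc, sent) in term_sets[t]}
        )
        size = lambda s: len({doc for (doc, _) in s})
    else:
        raise ValueError(f"unknown scope: {scope!r}")

    missing = [g for g in genes if g not in gene_sets] + [
        t for t in terms if t not in term_sets
    ]
    if missing:
        logger.warning(
            "%d ids absent from the occurrence tables score 0: %s",
            len(missing),
            ", ".join(missing[:10]),
        )

    scores = np.zeros((len(genes), len(terms)))
    for i, gene in enumerate(genes):
        if gene not in gene_sets:
            continue
        f_g = size(gene_sets[gene])
        for j, term in enumerate(terms):
            if term not in term_sets:
                continue
            f_t = size(term_sets[term])
            scores[i, j] = dice(f_g, f_t, joint(gene, term), denominator=denominator)
    return DiceMatrix(row_ids=list(genes), col_ids=list(terms), scores=scores)
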