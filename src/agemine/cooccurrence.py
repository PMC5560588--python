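"""Gene–term co-occurrence counting and aging-gene calling.

Two scopes are supported.  At *sentence* scope a pair counts in a document
iff gene and term share at least one sentence (high precision); at
*abstract* scope it suffices that both appear anywhere in the document
(high recall).  Counts are numbers of distinct documents, never hit
multiplicities, so sentence-scope counts are bounded above by
abstract-scope counts for every pair — the structural relation between the
two columns of the aging-term count table.

A gene is *called* aging-related at a scope if it co-occurs with at least
one aging-related term there; the per-gene evidence lists every matched
term with its document count.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

SCOPES = ("sentence", "abstract")

PAIR_COLUMNS = ["entity_a", "entity_b", "scope", "doc_count"]


def _check_scope(scope: str) -> None:
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}, got {scope!r}")


def cooccurrences(
    occ_a: pd.DataFrame, occ_b: pd.DataFrame, scope: str
) -> pd.DataFrame:
    """Count distinct documents where entity pairs jointly occur.

    At sentence scope the join is on (doc_id, sentence_index); at abstract
    scope on doc_id alone.  Both tables must come from the same document
    store.
    """
    _check_scope(scope)
    store_a = occ_a.attrs.get("store_id")
    store_b = occ_b.attrs.get("store_id")
    if store_a and store_b and store_a != store_b:
        raise ValueError(
            f"occurrence tables come from different stores ({store_a} vs {store_b})"
        )

    if occ_a.empty or occ_b.empty:
        empty = pd.DataFrame(columns=PAIR_COLUMNS)
        empty["doc_count"] = empty["doc_count"].astype(int)
        return empty

    keys = ["doc_id"] if scope == "abstract" else ["doc_id", "sentence_index"]
    left = occ_a[["entity_id", *keys]].rename(columns={"entity_id": "entity_a"})
    right = occ_b[["entity_id", *keys]].rename(columns={"entity_id": "entity_b"})
    joined = left.merge(right, on=keys)
    if joined.empty:
        empty = pd.DataFrame(columns=PAIR_COLUMNS)
        empty["doc_count"] = empty["doc_count"].astype(int)
        return empty

    pairs = (
        joined.groupby(["entity_a", "entity_b"])["doc_id"]
        .nunique()
        .reset_index(name="doc_count")
    )
    pairs.insert(2, "scope", scope)
    return pairs.sort_values(["entity_a", "entity_b"]).reset_index(drop=True)


def _term_ids(terms) -> set[str]:
    if isinstance(terms, Mapping):
        return set(terms.keys())
    out = set()
    for term in terms:
        out.add(term if isinstance(term, str) else term.term_id)
    return out


def identify_aging_genes(
    pairs: pd.DataFrame, terms
) -> dict[str, dict[str, int]]:
    """Call aging-related genes from a pair table at a single scope.

    A gene qualifies iff it is paired with at least one aging-related term.
    Returns gene_id -> {term_id: doc_count} evidence; pairs with entities
    outside *terms* (e.g. diseases) contribute nothing.
    """
    wanted = _term_ids(terms)
    if not pairs.empty and pairs["scope"].nunique() > 1:
        raise ValueError("pair table mixes scopes; call genes per scope")
    evidence: dict[str, dict[str, int]] = {}
    for row in pairs.itertuples(index=False):
        if row.entity_b in wanted:
            evidence.setdefault(row.entity_a, {})[row.entity_b] = int(row.doc_count)
    return evidence


def per_term_gene_counts(pairs: pd.DataFrame, terms) -> pd.DataFrame:
    """Distinct-gene count per aging term; terms absent from the corpus get 0."""
    wanted = sorted(_term_ids(terms))
    if pairs.empty:
        counts = {}
    else:
        sub = pairs[pairs["entity_b"].isin(wanted)]
        counts = sub.groupby("entity_b")["entity_a"].nunique().to_dict()
    return pd.DataFrame(
        {"term_id": wanted, "n_genes": [int(counts.get(t, 0)) for t in wanted]}
    )


def per_term_gene_sets(pairs: pd.DataFrame, terms) -> dict[str, set[str]]:
    """The distinct gene set behind each term's count."""
    wanted = _term_ids(terms)
    sets: dict[str, set[str]] = {t: set() for t in wanted}
    for row in pairs.itertuples(index=False):
        if row.entity_b in wanted:
            sets[row.entity_b].add(row.entity_a)
    return sets


def term_coverage_curve(
    term_gene_sets: Mapping[str, set[str]],
    ordering: Sequence[str] | str = "greedy",
) -> tuple[list[str], list[int]]:
    """Cumulative number of distinct genes covered by the first k terms.

    ``ordering`` is either an explicit term sequence or ``"greedy"``: pick,
    at each step, the term adding the most new genes (ties broken
    alphabetically).  The final value equals the size of the union of all
    sets regardless of ordering.
    """
    if isinstance(ordering, str):
        if ordering != "greedy":
            raise ValueError(f"unknown ordering: {ordering!r}")
        remaining = dict(term_gene_sets)
        covered: set[str] = set()
        order: list[str] = []
        while remaining:
            term = min(
                sorted(remaining), key=lambda t: (-len(remaining[t] - covered), t)
            )
            order.append(term)
            covered |= remaining.pop(term)
    else:
        order = list(ordering)

    cumulative: list[int] = []
    covered = set()
    for term in order:
        covered |= set(term_gene_sets.get(term, set()))
        cumulative.append(len(covered))
    return order, cumulative


def genes_with_all_terms(pairs: pd.DataFrame, term_subset: Iterable[str]) -> set[str]:
    """Genes paired with *every* term in the subset (intersection over terms)."""
    subset = sorted(_term_ids(term_subset))
    if not subset:
        raise ValueError("term_subset must be non-empty")
    sets = per_term_gene_sets(pairs, subset)
    result = sets[subset[0]]
    for term in subset[1:]:
        result = result & sets[term]
    return set(result)
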