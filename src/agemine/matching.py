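"""Keyword search and neighbor-search disambiguation.

``keyword_match`` records every whole-token hit of a dictionary surface form
in a sentence of the store, as rows (entity_id, doc_id, sentence_index).
Gene symbols are acronym-like, so their matching is case-sensitive by
default; disease and aging-term matching is case-insensitive.

``neighbor_filter`` then removes false-positive gene hits: a symbol
occurrence survives only if at least one word from the gene's neighbor
search word set — the words its full names abbreviate — appears in the same
sentence.  This is what rescues symbols that collide with English words
(the gene IMPACT in "the impact of diet" carries no neighbor word and is
discarded; ALK next to "anaplastic lymphoma" is kept).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from ._text import surface_pattern, tokenize
from .corpus import DocumentStore
from .dictionaries import GeneRecord, NeighborWordSet, TermRecord

OCCURRENCE_COLUMNS = ["entity_id", "doc_id", "sentence_index"]


def empty_occurrence_table(store: DocumentStore | None = None) -> pd.DataFrame:
    table = pd.DataFrame(columns=OCCURRENCE_COLUMNS)
    table["sentence_index"] = table["sentence_index"].astype(int)
    if store is not None:
        table.attrs["store_id"] = store.store_id
    return table


def _surface_map(dictionary, case_sensitive: bool | None) -> tuple[dict, bool]:
    """Map surface form -> set of entity ids; resolve the case convention."""
    if isinstance(dictionary, Mapping):
        entries: Iterable = dictionary.values()
    else:
        entries = dictionary
    entries = list(entries)

    surfaces: dict[str, set[str]] = {}
    inferred_case = False
    for entry in entries:
        if isinstance(entry, GeneRecord):
            inferred_case = True
            for surface in entry.surface_forms:
                surfaces.setdefault(surface, set()).add(entry.gene_id)
        elif isinstance(entry, TermRecord):
            for surface in entry.surface_forms:
                surfaces.setdefault(surface, set()).add(entry.term_id)
        else:
            raise TypeError(f"unsupported dictionary entry: {type(entry).__name__}")
    if case_sensitive is None:
        case_sensitive = inferred_case
    return surfaces, case_sensitive


def keyword_match(
    store: DocumentStore,
    dictionary,
    case_sensitive: bool | None = None,
) -> pd.DataFrame:
    """Find all whole-token dictionary hits in the store.

    Returns a deduplicated occurrence table; one row per
    (entity, document, sentence) regardless of hit multiplicity within the
    sentence.  Multiword surface forms match as contiguous token sequences.
    """
    surfaces, case_sensitive = _surface_map(dictionary, case_sensitive)
    compiled = {
        surface: surface_pattern(surface, case_sensitive) for surface in surfaces
    }

    rows: set[tuple[str, str, int]] = set()
    for document in store:
        for index, sentence in enumerate(document.sentences):
            lowered = sentence.lower()
            for surface, pattern in compiled.items():
                if surface.lower() not in lowered:
                    continue
                if pattern.search(sentence):
                    for entity_id in surfaces[surface]:
                        rows.add((entity_id, document.doc_id, index))

    table = pd.DataFrame(sorted(rows), columns=OCCURRENCE_COLUMNS)
    if table.empty:
        table = empty_occurrence_table()
    table.attrs["store_id"] = store.store_id
    return table


def neighbor_filter(
    gene_occurrences: pd.DataFrame,
    store: DocumentStore,
    neighbor_sets: Mapping[str, NeighborWordSet],
    empty_set_policy: str = "keep",
) -> pd.DataFrame:
    """Drop gene occurrences lacking a neighbor word in the same sentence.

    A row survives iff one of the gene's neighbor words occurs
    (case-insensitive, whole-token) in the sentence carrying the symbol.
    Genes whose word set is empty are unfilterable; ``empty_set_policy``
    decides whether their rows pass (``"keep"``, default) or are dropped
    (``"drop"``).  The filter is idempotent and per-gene independent.
    """
    if empty_set_policy not in ("keep", "drop"):
        raise ValueError(f"unknown empty_set_policy: {empty_set_policy!r}")

    keep_mask = []
    for row in gene_occurrences.itertuples(index=False):
        entry = neighbor_sets.get(row.entity_id)
        if entry is None:
            raise KeyError(f"gene {row.entity_id} has no neighbor word set")
        if not entry.words:
            keep_mask.append(empty_set_policy == "keep")
            continue
        sentence = store[row.doc_id].sentences[row.sentence_index]
        tokens = set(tokenize(sentence))
        keep_mask.append(bool(entry.words & tokens))

    filtered = gene_occurrences.loc[keep_mask].reset_index(drop=True)
    filtered.attrs["store_id"] = gene_occurrences.attrs.get("store_id")
    return filtered


def write_occurrences(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_occurrences(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"entity_id": str, "doc_id": str})
    table["sentence_index"] = table["sentence_index"].astype(int)
    return table
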