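"""Controlled vocabularies: genes, diseases, and aging-related terms.

Three dictionaries drive the literature mining:

* a **gene dictionary** built from an NCBI ``gene_info``-style table,
  restricted to protein-coding genes, with primary-symbol/alias conflicts
  resolved (an alias identical to another gene's primary symbol is deleted);
* a **disease dictionary** built from a CTD-style table, keeping only
  diseases with MeSH/OMIM identifiers and pruning ambiguous or
  general-English synonyms;
* a fixed list of **aging-related terms** (45 curated surface strings such
  as ``SENESCENCE`` and ``LONG-LIVED``) shipped as a package fixture.

Each protein-coding gene additionally gets a *neighbor search word set*: the
informative tokens of its full names, used downstream to discard
false-positive symbol hits (e.g. the gene ``IMPACT`` inside the phrase
"the impact of diet").
"""

from __future__ import annotations

import importlib.resources
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from ._text import tokenize

EMPTY_FIELD = "-"
LIST_DELIMITER = "|"

GENE_COLUMNS = ("GeneID", "Symbol", "Synonyms", "description", "type_of_gene")
DISEASE_COLUMNS = ("DiseaseName", "DiseaseID", "Synonyms", "SlimMappings")


class DictionaryError(ValueError):
    """Structural problem in a dictionary source table."""


@dataclass(frozen=True)
class GeneRecord:
    """One protein-coding gene with its symbol, aliases and full names."""

    gene_id: str
    primary_symbol: str
    aliases: frozenset[str]
    full_names: frozenset[str]
    gene_type: str = "protein-coding"

    def __post_init__(self) -> None:
        if not self.primary_symbol:
            raise DictionaryError(f"gene {self.gene_id}: empty primary symbol")
        if self.primary_symbol in self.aliases:
            raise DictionaryError(
                f"gene {self.gene_id}: primary symbol listed among its own aliases"
            )

    @property
    def surface_forms(self) -> frozenset[str]:
        return self.aliases | {self.primary_symbol}


@dataclass(frozen=True)
class NeighborWordSet:
    """Lowercase words abbreviated into a gene symbol, minus generic ones."""

    gene_id: str
    words: frozenset[str]


@dataclass(frozen=True)
class TermRecord:
    """A disease, aging-term, or cause entry with its surface forms."""

    term_id: str
    canonical_form: str
    surface_forms: frozenset[str]
    category: str

    def __post_init__(self) -> None:
        if not self.surface_forms:
            raise DictionaryError(f"term {self.term_id}: no surface forms")
        if self.canonical_form not in self.surface_forms:
            raise DictionaryError(
                f"term {self.term_id}: canonical form missing from surface forms"
            )


def _read_table(source, required: Iterable[str]) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        table = source
    else:
        table = pd.read_csv(source, sep="\t", dtype=str, comment=None)
        # NCBI-style headers open with '#'
        table.columns = [c.lstrip("#") for c in table.columns]
    for column in required:
        if column not in table.columns:
            raise DictionaryError(f"missing required column: {column!r}")
    return table.fillna(EMPTY_FIELD)


def _split_list_field(value: str) -> list[str]:
    if not value or value == EMPTY_FIELD:
        return []
    return [v.strip() for v in value.split(LIST_DELIMITER) if v.strip()]


def build_gene_dictionary(
    gene_table,
    *,
    protein_coding_only: bool = True,
    allow_multi_mapping: bool = False,
) -> dict[str, GeneRecord]:
    """Build the gene dictionary from an NCBI ``gene_info``-style table.

    Parameters
    ----------
    gene_table
        Path or DataFrame with at least the columns ``GeneID``, ``Symbol``,
        ``Synonyms`` (pipe-delimited, ``-`` for empty), ``description`` and
        ``type_of_gene``.  An ``Other_designations`` column, when present,
        contributes additional full names.
    protein_coding_only
        Keep only rows whose ``type_of_gene`` equals ``protein-coding``.
    allow_multi_mapping
        When False (default), an alias shared verbatim by several genes is
        deleted from all of them so every surviving surface form maps to
        exactly one gene.

    Conflict resolution: any alias string equal to the primary symbol of a
    *different* gene is removed from the alias set (the primary owner keeps
    it).  The procedure is idempotent.
    """
    table = _read_table(gene_table, GENE_COLUMNS)
    if protein_coding_only:
        table = table[table["type_of_gene"] == "protein-coding"]

    if table["GeneID"].duplicated().any():
        dupes = table.loc[table["GeneID"].duplicated(), "GeneID"].tolist()
        raise DictionaryError(f"duplicate gene_id rows: {dupes}")

    rows = []
    for _, row in table.iterrows():
        names = set()
        if row["description"] != EMPTY_FIELD:
            names.add(row["description"].strip())
        if "Other_designations" in table.columns:
            names.update(_split_list_field(row["Other_designations"]))
        rows.append(
            (
                str(row["GeneID"]),
                row["Symbol"].strip(),
                set(_split_list_field(row["Synonyms"])),
                names,
            )
        )

    primary_symbols = {symbol for _, symbol, _, _ in rows}
    alias_owners: Counter[str] = Counter()
    for _, _, aliases, _ in rows:
        alias_owners.update(aliases)

    records: dict[str, GeneRecord] = {}
    for gene_id, symbol, aliases, names in rows:
        kept = set()
        for alias in aliases:
            if alias == symbol:
                continue  # invariant: symbol never doubles as its own alias
            if alias in primary_symbols:
                continue  # alias collides with another gene's primary symbol
            if not allow_multi_mapping and alias_owners[alias] > 1:
                continue  # ambiguous alias: shared by several genes
            kept.add(alias)
        records[gene_id] = GeneRecord(
            gene_id=gene_id,
            primary_symbol=symbol,
            aliases=frozenset(kept),
            full_names=frozenset(names),
        )
    return records


def default_stoplist() -> frozenset[str]:
    """Shipped list of words too generic to anchor a gene symbol."""
    text = (
        importlib.resources.files("agemine.data")
        .joinpath("neighbor_stoplist.txt")
        .read_text(encoding="utf-8")
    )
    return frozenset(
        line.strip().lower()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


def build_neighbor_word_sets(
    genes: Mapping[str, GeneRecord] | Iterable[GeneRecord],
    stoplist: Iterable[str] | None = None,
    min_word_len: int = 3,
    max_gene_frequency: int | None = None,
) -> dict[str, NeighborWordSet]:
    """Derive each gene's neighbor search word set from its full names.

    The full names are split at the delimiter set, lowercased, and filtered:
    stoplist members, tokens shorter than *min_word_len*, and the gene's own
    symbol are removed.  With *max_gene_frequency* set, tokens occurring in
    the names of more than that many genes are also dropped — a frequency
    proxy for "not specific to this gene".  An empty word set is legal.
    """
    if isinstance(genes, Mapping):
        gene_list = list(genes.values())
    else:
        gene_list = list(genes)
    stop = frozenset(w.lower() for w in stoplist) if stoplist is not None else frozenset()

    raw: dict[str, set[str]] = {}
    for gene in gene_list:
        words: set[str] = set()
        for name in sorted(gene.full_names):  # order-insensitive by set union
            words.update(tokenize(name))
        raw[gene.gene_id] = words

    too_common: set[str] = set()
    if max_gene_frequency is not None:
        document_frequency: Counter[str] = Counter()
        for words in raw.values():
            document_frequency.update(words)
        too_common = {
            w for w, n in document_frequency.items() if n > max_gene_frequency
        }

    out: dict[str, NeighborWordSet] = {}
    for gene in gene_list:
        words = {
            w
            for w in raw[gene.gene_id]
            if len(w) >= min_word_len
            and w not in stop
            and w not in too_common
            and w != gene.primary_symbol.lower()
        }
        out[gene.gene_id] = NeighborWordSet(gene_id=gene.gene_id, words=frozenset(words))
    return out


def default_general_words() -> frozenset[str]:
    """Shipped English words that collide with disease synonyms."""
    text = (
        importlib.resources.files("agemine.data")
        .joinpath("general_words.txt")
        .read_text(encoding="utf-8")
    )
    return frozenset(
        line.strip().lower()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


def build_disease_dictionary(
    disease_table,
    general_word_list: Iterable[str] | None = None,
    *,
    animal_disease_flag: str = "Animal disease",
) -> dict[str, TermRecord]:
    """Build the disease dictionary from a CTD-style table.

    Rules applied in order: rows flagged as animal diseases in
    ``SlimMappings`` are removed; primary names must carry a MeSH or OMIM
    identifier; synonyms shared by more than one disease are deleted from
    all of them; synonyms spelled like general English words are deleted
    (the canonical name itself is always kept).
    """
    table = _read_table(disease_table, DISEASE_COLUMNS)
    general = (
        frozenset(w.lower() for w in general_word_list)
        if general_word_list is not None
        else default_general_words()
    )

    rows = []
    for _, row in table.iterrows():
        slims = {s.lower() for s in _split_list_field(row["SlimMappings"])}
        if animal_disease_flag.lower() in slims:
            continue
        disease_id = str(row["DiseaseID"]).strip()
        if not (disease_id.startswith("MESH:") or disease_id.startswith("OMIM:")):
            continue
        rows.append(
            (
                disease_id,
                row["DiseaseName"].strip(),
                set(_split_list_field(row["Synonyms"])),
            )
        )

    synonym_owners: Counter[str] = Counter()
    for _, _, synonyms in rows:
        synonym_owners.update(s.lower() for s in synonyms)

    records: dict[str, TermRecord] = {}
    for disease_id, name, synonyms in rows:
        kept = {
            s
            for s in synonyms
            if synonym_owners[s.lower()] == 1 and s.lower() not in general
        }
        records[disease_id] = TermRecord(
            term_id=disease_id,
            canonical_form=name,
            surface_forms=frozenset(kept | {name}),
            category="disease",
        )
    return records


def load_aging_terms(term_list=None) -> dict[str, TermRecord]:
    """Load the aging-related term dictionary.

    Without an argument the packaged 45-term fixture is used.  Accepts a
    path or an iterable of lines; duplicate lines (case-insensitive)
    collapse to one record.  Term ids are the uppercased canonical strings.
    """
    if term_list is None:
        text = (
            importlib.resources.files("agemine.data")
            .joinpath("aging_terms.txt")
            .read_text(encoding="utf-8")
        )
        lines: Iterable[str] = text.splitlines()
    elif isinstance(term_list, (str, Path)):
        lines = Path(term_list).read_text(encoding="utf-8").splitlines()
    else:
        lines = term_list

    records: dict[str, TermRecord] = {}
    for line in lines:
        term = line.strip()
        if not term:
            continue
        term_id = term.upper()
        if term_id in records:
            continue
        records[term_id] = TermRecord(
            term_id=term_id,
            canonical_form=term,
            surface_forms=frozenset({term}),
            category="aging-term",
        )
    if not records:
        raise DictionaryError("aging-term list is empty")
    return records


def write_gene_dictionary(genes: Mapping[str, GeneRecord], path) -> None:
    """Export a flat surface-form table.

    One row per surface form with a ``Synonym`` flag column: 1 marks the
    primary gene symbol, 0 marks a synonym.
    """
    rows = []
    for gene in genes.values():
        rows.append({"GeneID": gene.gene_id, "Surface": gene.primary_symbol, "Synonym": 1})
        for alias in sorted(gene.aliases):
            rows.append({"GeneID": gene.gene_id, "Surface": alias, "Synonym": 0})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
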