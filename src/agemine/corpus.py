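"""Abstract corpus ingestion and the indexed document store.

Two input dialects are accepted: MEDLINE flat-file records (``PMID-`` /
``AB-`` fields, parsed with Biopython) and a simplified one-record-per-line
JSON dialect (``{"id": ..., "abstract": ...}``) used for fixtures.  Records
without an identifier or a non-empty abstract are dropped at ingest, and
each surviving abstract is segmented into sentences once; all downstream
occurrence tables refer to (doc_id, sentence_index) pairs of this store.

Segmentation is a deterministic rule-based splitter: a break occurs at
``.?!`` followed by whitespace and a capital letter or digit, unless the
preceding token is a protected abbreviation (``e.g.``, ``et al.``, ...).
Corpus-scale sentence counts are therefore segmenter-dependent; the splitter
is pluggable for anyone who needs a different convention.
"""

from __future__ import annotations

import hashlib
import io
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator

from Bio import Medline

logger = logging.getLogger(__name__)

#: Tokens (lowercase, final period included) that never end a sentence.
PROTECTED_ABBREVIATIONS = frozenset(
    {
        "e.g.",
        "i.e.",
        "et al.",
        "al.",
        "vs.",
        "cf.",
        "ca.",
        "approx.",
        "fig.",
        "figs.",
        "no.",
        "nos.",
        "dr.",
        "prof.",
        "st.",
        "resp.",
        "wt.",
        "spp.",
        "sp.",
    }
)

_BREAK = re.compile(r"([.?!]+)(\s+)(?=[A-Z0-9])")


def segment_sentences(
    text: str, protected: frozenset[str] = PROTECTED_ABBREVIATIONS
) -> list[str]:
    """Split an abstract into sentences; deterministic for fixed input.

    The concatenation of the returned sentences, joined with single spaces,
    reconstructs the text modulo inter-sentence whitespace.
    """
    text = text.strip()
    if not text:
        return []
    sentences: list[str] = []
    start = 0
    for match in _BREAK.finditer(text):
        end = match.end(1)
        prefix = text[start:end]
        last_token = prefix.rsplit(None, 1)[-1].lower() if prefix.split() else ""
        if last_token in protected or (
            # two-token abbreviations such as "et al."
            len(prefix.split()) >= 2
            and " ".join(prefix.split()[-2:]).lower() in protected
        ):
            continue
        sentences.append(prefix.strip())
        start = match.end()
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


@dataclass(frozen=True)
class Document:
    """One abstract, segmented into an ordered list of sentences."""

    doc_id: str
    sentences: tuple[str, ...]

    @property
    def n_sentences(self) -> int:
        return len(self.sentences)


@dataclass
class DocumentStore:
    """Indexed collection of segmented abstracts with a stable identity.

    ``store_id`` is a content hash over (doc_id, sentences); two stores
    built from the same corpus are interchangeable and occurrence tables
    carry the id so cross-store joins can be rejected.
    """

    documents: dict[str, Document] = field(default_factory=dict)
    n_input_records: int = 0
    n_skipped: int = 0

    def add(self, document: Document) -> None:
        if document.doc_id in self.documents:
            logger.warning("duplicate doc_id %s: keeping the later record", document.doc_id)
        self.documents[document.doc_id] = document

    def __len__(self) -> int:
        return len(self.documents)

    def __contains__(self, doc_id: str) -> bool:
        return doc_id in self.documents

    def __getitem__(self, doc_id: str) -> Document:
        return self.documents[doc_id]

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents.values())

    @property
    def store_id(self) -> str:
        digest = hashlib.md5()
        for doc_id in sorted(self.documents):
            digest.update(doc_id.encode())
            for sentence in self.documents[doc_id].sentences:
                digest.update(b"\x1f" + sentence.encode())
        return digest.hexdigest()[:16]

    def save(self, path) -> None:
        """Write the store as TSV rows (doc_id, sentence_index, sentence)."""
        with open(path, "w", encoding="utf-8") as handle:
            handle.write("doc_id\tsentence_index\tsentence\n")
            for document in self:
                for index, sentence in enumerate(document.sentences):
                    handle.write(f"{document.doc_id}\t{index}\t{sentence}\n")

    @classmethod
    def load(cls, path) -> "DocumentStore":
        store = cls()
        grouped: dict[str, list[str]] = {}
        with open(path, encoding="utf-8") as handle:
            next(handle)  # header
            for line in handle:
                doc_id, _, sentence = line.rstrip("\n").split("\t", 2)
                grouped.setdefault(doc_id, []).append(sentence)
        for doc_id, sentences in grouped.items():
            store.add(Document(doc_id=doc_id, sentences=tuple(sentences)))
        store.n_input_records = len(store)
        return store


def _parse_simple(lines: Iterable[str]) -> Iterator[dict]:
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        try:
            record = json.loads(line)
        except json.JSONDecodeError:
            yield {"__error__": f"line {lineno}: unparseable record"}
            continue
        yield {"PMID": str(record.get("id", "")), "AB": record.get("abstract", "")}


def _parse_medline(handle) -> Iterator[dict]:
    for record in Medline.parse(handle):
        yield {"PMID": record.get("PMID", ""), "AB": record.get("AB", "")}


def ingest_corpus(
    source,
    fmt: str = "auto",
    segmenter: Callable[[str], list[str]] = segment_sentences,
) -> DocumentStore:
    """Build a DocumentStore from a MEDLINE or simple-dialect corpus.

    Only records with both an identifier and a non-empty abstract are kept;
    the store reports how many input records were seen and skipped.
    Unparseable records are logged and counted, never fatal.
    """
    if isinstance(source, Path) or (
        isinstance(source, str)
        and source
        and "\n" not in source
        and Path(source).is_file()
    ):
        handle: io.TextIOBase = open(source, encoding="utf-8")
        close = True
    elif isinstance(source, str):
        handle, close = io.StringIO(source), False
    elif hasattr(source, "read"):
        handle, close = source, False
    else:
        handle, close = io.StringIO("\n".join(source)), False

    try:
        text = handle.read()
    finally:
        if close:
            handle.close()

    if fmt == "auto":
        first = next((l for l in text.splitlines() if l.strip()), "")
        fmt = "simple" if first.lstrip().startswith("{") else "medline"

    if fmt == "simple":
        records = _parse_simple(text.splitlines())
    elif fmt == "medline":
        records = _parse_medline(io.StringIO(text))
    else:
        raise ValueError(f"unknown corpus format: {fmt!r}")

    store = DocumentStore()
    for record in records:
        store.n_input_records += 1
        if "__error__" in record:
            logger.warning("skipping record: %s", record["__error__"])
            store.n_skipped += 1
            continue
        doc_id, abstract = record["PMID"], (record["AB"] or "").strip()
        if not doc_id or not abstract:
            store.n_skipped += 1
            continue
        sentences = tuple(segmenter(abstract))
        if not sentences:
            store.n_skipped += 1
            continue
        store.add(Document(doc_id=doc_id, sentences=sentences))
    logger.info(
        "ingested %d/%d records (%d skipped)",
        len(store),
        store.n_input_records,
        store.n_skipped,
    )
    return store
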