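"""Pathway-hypothesis gene-set expansion.

The pathway hypothesis: a gene is aging-related if it occurs in the same
pathway as an already-called aging-related gene.  Expansion is a single
round from the literature-derived seeds — no transitive closure, since the
seeds themselves carry false positives that closure would compound.
Pathway membership is exchanged in GMT (one line per set: id, description,
member genes).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    pathway_name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"pathway {self.pathway_id} has no members")


def read_gmt(source) -> dict[str, Pathway]:
    """Read a GMT file (or iterable of lines) into pathway records."""
    if isinstance(source, (str, Path)):
        lines: Iterable[str] = Path(source).read_text(encoding="utf-8").splitlines()
    else:
        lines = source
    pathways: dict[str, Pathway] = {}
    for line in lines:
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (need id, name, >=1 member): {line!r}")
        pathway_id, name, *members = fields
        if pathway_id in pathways:
            raise ValueError(f"duplicate pathway_id: {pathway_id}")
        pathways[pathway_id] = Pathway(
            pathway_id=pathway_id,
            pathway_name=name,
            members=frozenset(m for m in members if m),
        )
    return pathways


def write_gmt(pathways: Mapping[str, Pathway], path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for pathway in pathways.values():
            members = "\t".join(sorted(pathway.members))
            handle.write(f"{pathway.pathway_id}\t{pathway.pathway_name}\t{members}\n")


def expand_by_pathway(
    seeds: Iterable[str], pathways: Mapping[str, Pathway] | Iterable[Pathway]
) -> tuple[set[str], dict[str, set[tuple[str, str]]]]:
    """One round of pathway expansion from a seed gene set.

    Returns ``(expanded, provenance)`` where ``expanded`` is the seeds plus
    every gene sharing a pathway with at least one seed, and ``provenance``
    maps each *added* gene to its (pathway_id, seed_gene) justifications.
    Seeds absent from every pathway simply add nothing.
    """
    seed_set = set(seeds)
    if not seed_set:
        raise ValueError("seed gene set is empty")
    if isinstance(pathways, Mapping):
        pathway_list = list(pathways.values())
    else:
        pathway_list = list(pathways)

    provenance: dict[str, set[tuple[str, str]]] = {}
    for pathway in pathway_list:
        hit_seeds = pathway.members & seed_set
        if not hit_seeds:
            continue
        for gene in pathway.members - seed_set:
            entry = provenance.setdefault(gene, set())
            entry.update((pathway.pathway_id, seed) for seed in hit_seeds)

    expanded = seed_set | set(provenance)
    return expanded, provenance


def write_provenance(provenance: Mapping[str, set[tuple[str, str]]], path) -> None:
    """TSV export: one row per (added gene, pathway, seed) justification."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("gene_id\tpathway_id\tseed_gene\n")
        for gene in sorted(provenance):
            for pathway_id, seed in sorted(provenance[gene]):
                handle.write(f"{gene}\t{pathway_id}\t{seed}\n")
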