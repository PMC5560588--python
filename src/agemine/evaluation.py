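"""Validation of gene calls: curation CIs, benchmark coverage, annotation.

Calling genes from co-occurrence inevitably admits false positives, so the
calls are audited by sampling genes uniformly for manual curation and
summarizing the curated proportion with a normal-approximation (Wald)
confidence interval

    R - z * sqrt(R(1-R)/n)  <  p  <  R + z * sqrt(R(1-R)/n),

z = 1.96 for the conventional 95% level.  The Wald form is the primary
interval; the Wilson score interval is available as an alternative for
proportions near the boundary.  Coverage against a curated benchmark list
(GenAge-style) and intersection with labeled annotation lists (drug
targets, mitochondrial genes, ...) round out the validation toolkit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np


@dataclass(frozen=True)
class ProportionCI:
    """A proportion with its confidence interval, bounds clamped to [0, 1]."""

    n: int
    successes: int
    z: float
    R: float
    lower: float
    upper: float
    method: str = "wald"

    def as_percent(self, decimals: int = 1) -> tuple[float, float]:
        return (round(100 * self.lower, decimals), round(100 * self.upper, decimals))

    def __str__(self) -> str:
        lo, hi = self.as_percent()
        return f"{lo:.1f}% to {hi:.1f}%"


def proportion_ci(
    n: int, successes: int, z: float = 1.96, method: str = "wald"
) -> ProportionCI:
    """Confidence interval for a curated proportion successes/n."""
    if n < 1:
        raise ValueError("n must be a positive integer")
    if not 0 <= successes <= n:
        raise ValueError(f"successes must lie in [0, {n}], got {successes}")

    R = successes / n
    if method == "wald":
        half = z * math.sqrt(R * (1.0 - R) / n)
        lower, upper = R - half, R + half
    elif method == "wilson":
        denom = 1.0 + z**2 / n
        center = (R + z**2 / (2 * n)) / denom
        half = (z / denom) * math.sqrt(R * (1.0 - R) / n + z**2 / (4 * n**2))
        lower, upper = center - half, center + half
    else:
        raise ValueError(f"unknown method: {method!r}")

    return ProportionCI(
        n=n,
        successes=successes,
        z=z,
        R=R,
        lower=max(0.0, lower),
        upper=min(1.0, upper),
        method=method,
    )


@dataclass(frozen=True)
class CoverageReport:
    """How much of a benchmark gene list the candidate set recovers."""

    candidate_size: int
    benchmark_size: int
    overlap: int
    coverage_fraction: float
    common_genes: frozenset[str]

    def __str__(self) -> str:
        return (
            f"{self.overlap}/{self.benchmark_size} benchmark genes covered "
            f"({100 * self.coverage_fraction:.1f}%)"
        )


def benchmark_coverage(
    candidates: Iterable[str], benchmark: Iterable[str]
) -> CoverageReport:
    """Fraction of the benchmark recovered by the candidate gene set."""
    candidate_set, benchmark_set = set(candidates), set(benchmark)
    if not benchmark_set:
        raise ValueError("benchmark gene set is empty")
    common = candidate_set & benchmark_set
    return CoverageReport(
        candidate_size=len(candidate_set),
        benchmark_size=len(benchmark_set),
        overlap=len(common),
        coverage_fraction=len(common) / len(benchmark_set),
        common_genes=frozenset(common),
    )


def sample_for_curation(genes: Iterable[str], k: int, seed: int) -> list[str]:
    """Uniform sample of k genes without replacement, reproducible by seed.

    Drawing several samples with distinct seeds reproduces the repeated
    random-audit design used to bracket the true aging-related proportion.
    """
    pool = sorted(set(genes))
    if k > len(pool):
        raise ValueError(f"cannot sample {k} from {len(pool)} genes")
    rng = np.random.default_rng(seed)
    return [pool[i] for i in rng.choice(len(pool), size=k, replace=False)]


@dataclass(frozen=True)
class AnnotationReport:
    """Candidates carrying an external annotation (e.g. drug target)."""

    label: str
    count: int
    members: frozenset[str]


def annotate_gene_list(
    candidates: Iterable[str], annotation: Iterable[str], label: str = "annotated"
) -> AnnotationReport:
    """Intersection of the candidate set with a labeled annotation list."""
    members = frozenset(set(candidates) & set(annotation))
    return AnnotationReport(label=label, count=len(members), members=members)


def read_gene_list(path) -> set[str]:
    """Plain-text gene list, one identifier per line; '#' lines skipped."""
    out = set()
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out
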