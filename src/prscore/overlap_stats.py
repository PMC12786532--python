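"""Pairwise gene-sharing statistics and shared-core extraction.

Given the presence matrix, this module quantifies how much genetic material
pairs of diseases share (shared count, Jaccard index, overlap coefficient),
ranks genes by how many diseases hit them, and extracts "core" gene sets by
explicit, re-derivable rules: a frequency threshold, the intersection within
a disease cluster, the intersection of a cluster's cores across size strata,
and the intersection across clusters.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .core_matrix import GenePresenceMatrix

__all__ = [
    "OverlapResult",
    "CoreSet",
    "pairwise_overlap",
    "mean_pairwise_fraction",
    "gene_disease_frequency",
    "select_shared_core",
    "cluster_core_genes",
    "cross_stratum_core",
    "between_cluster_common",
    "overlap_table",
]


@dataclass(frozen=True)
class OverlapResult:
    """Sharing statistics for one unordered disease pair.

    jaccard = shared/union (0 when the union is empty); overlap_coef =
    shared/min(|A|, |B|) (0 when either set is empty).  Both are symmetric
    and jaccard <= overlap_coef always.
    """

    pair: tuple[str, str]
    n_shared: int
    n_union: int
    jaccard: float
    overlap_coef: float
    shared_genes: frozenset[str]


@dataclass(frozen=True)
class CoreSet:
    """A named gene set together with the rule that produced it."""

    label: str
    genes: frozenset[str]
    rule: str
    stratum_label: str = "all"

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "genes": sorted(self.genes),
            "rule": self.rule,
            "stratum_label": self.stratum_label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CoreSet":
        return cls(
            label=d["label"],
            genes=frozenset(d["genes"]),
            rule=d["rule"],
            stratum_label=d.get("stratum_label", "all"),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CoreSet":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _overlap(pair: tuple[str, str], a: set[str], b: set[str]) -> OverlapResult:
    shared = a & b
    union = a | b
    return OverlapResult(
        pair=pair,
        n_shared=len(shared),
        n_union=len(union),
        jaccard=len(shared) / len(union) if union else 0.0,
        overlap_coef=len(shared) / min(len(a), len(b)) if a and b else 0.0,
        shared_genes=frozenset(shared),
    )


def pairwise_overlap(matrix: GenePresenceMatrix) -> list[OverlapResult]:
    """One :class:`OverlapResult` per unordered disease pair, in
    lexicographic pair order."""
    sets = {d: matrix.trait_genes(d) for d in matrix.diseases}
    return [
        _overlap((a, b), sets[a], sets[b])
        for a, b in itertools.combinations(sorted(sets), 2)
    ]


def mean_pairwise_fraction(
    results: list[OverlapResult], fraction: str = "jaccard"
) -> float:
    """Mean shared-gene fraction over all pairs, as a percentage.

    ``fraction`` chooses the denominator convention: ``"jaccard"`` (shared
    over union, the default) or ``"overlap_coef"`` (shared over the smaller
    set).
    """
    if not results:
        raise ValueError("no pairs to average")
    if fraction not in ("jaccard", "overlap_coef"):
        raise ValueError(f"unknown fraction {fraction!r}")
    return 100.0 * sum(getattr(r, fraction) for r in results) / len(results)


def gene_disease_frequency(matrix: GenePresenceMatrix) -> list[tuple[str, int]]:
    """Genes ranked by the number of diseases hitting them.

    Sorted by count descending, ties broken lexicographically.
    """
    counts = matrix.frame.sum(axis=0)
    return sorted(
        ((gene, int(n)) for gene, n in counts.items()),
        key=lambda item: (-item[1], item[0]),
    )


def select_shared_core(matrix: GenePresenceMatrix, min_count: int) -> CoreSet:
    """Genes present in at least ``min_count`` diseases."""
    n_traits = len(matrix.diseases)
    if not (1 <= min_count <= n_traits):
        raise ValueError(f"min_count must lie in [1, {n_traits}], got {min_count}")
    genes = frozenset(
        gene for gene, n in gene_disease_frequency(matrix) if n >= min_count
    )
    return CoreSet(
        label=f"shared_core_min{min_count}",
        genes=genes,
        rule=f"disease frequency >= {min_count}",
        stratum_label=matrix.stratum_label,
    )


def cluster_core_genes(matrix: GenePresenceMatrix, cluster: set[str]) -> CoreSet:
    """Intersection of the member diseases' gene sets (|cluster| >= 2)."""
    unknown = set(cluster) - set(matrix.diseases)
    if unknown:
        raise ValueError(f"unknown traits in cluster: {sorted(unknown)}")
    if len(cluster) < 2:
        raise ValueError("a cluster core needs at least 2 member traits")
    members = sorted(cluster)
    genes = matrix.trait_genes(members[0])
    for trait in members[1:]:
        genes &= matrix.trait_genes(trait)
    return CoreSet(
        label="cluster:" + "+".join(members),
        genes=frozenset(genes),
        rule="intersection over cluster members " + ",".join(members),
        stratum_label=matrix.stratum_label,
    )


def cross_stratum_core(cores: list[CoreSet]) -> CoreSet:
    """Intersection of one cluster's cores across size strata."""
    if len(cores) < 2:
        raise ValueError("need cores from at least 2 strata")
    labels = {c.label for c in cores}
    if len(labels) != 1:
        raise ValueError(f"cores belong to different clusters: {sorted(labels)}")
    genes = frozenset.intersection(*(c.genes for c in cores))
    strata = ",".join(c.stratum_label for c in cores)
    return CoreSet(
        label=cores[0].label,
        genes=genes,
        rule=f"intersection across strata {strata}",
        stratum_label="all",
    )


def between_cluster_common(cores: list[CoreSet]) -> CoreSet:
    """Genes common to every cluster's core (expected empty when clusters
    reflect genuinely distinct mechanisms)."""
    if len(cores) < 2:
        raise ValueError("need cores from at least 2 clusters")
    genes = frozenset.intersection(*(c.genes for c in cores))
    return CoreSet(
        label="between_clusters",
        genes=genes,
        rule="intersection across cluster cores "
        + ";".join(c.label for c in cores),
        stratum_label=cores[0].stratum_label,
    )


def overlap_table(results: list[OverlapResult]) -> pd.DataFrame:
    """Flat table of pairwise statistics, ready for TSV export."""
    return pd.DataFrame(
        {
            "trait_a": [r.pair[0] for r in results],
            "trait_b": [r.pair[1] for r in results],
            "n_shared": [r.n_shared for r in results],
            "n_union": [r.n_union for r in results],
            "jaccard": [r.jaccard for r in results],
            "overlap_coef": [r.overlap_coef for r in results],
            "shared_genes": [",".join(sorted(r.shared_genes)) for r in results],
        }
    )
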