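"""Core-based plausibility screening of a candidate polygenic score.

The idea: scores for related diseases keep hitting the same shared "core"
genes, and the expected share of core genes in a score depends on how many
variants it has.  A new score can therefore be screened by (1) computing the
fraction of its genes that fall in a reference core, (2) comparing that
fraction with the distribution observed over size-matched reference scores,
and (3) flagging strong deviations in either direction.  A core-depleted
score may indicate the underlying GWAS missed biology worth rechecking; the
verdict is a screening signal, not a claim of clinical (in)validity.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

from .gene_annotation import GeneMap
from .overlap_stats import CoreSet
from .pgs_io import ScoringFile, SizeStratum

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceBin",
    "VerificationReport",
    "core_overlap_fraction",
    "reference_distribution",
    "verify_score",
]


@dataclass(frozen=True)
class ReferenceBin:
    """Mean/sd of the core-overlap fraction over references in one size bin.

    A bin with fewer than 2 references is kept but flagged unusable.
    """

    label: str
    mean: float
    sd: float
    n: int

    @property
    def usable(self) -> bool:
        return self.n >= 2


@dataclass(frozen=True)
class VerificationReport:
    """Outcome of screening one candidate score against a reference core."""

    score_id: str
    n_genes: int
    core_hits: int
    core_fraction: float
    size_bin: str
    ref_mean: float
    ref_sd: float
    z: float
    verdict: str  # typical | core-depleted | core-enriched

    def to_dict(self) -> dict:
        return {
            "score_id": self.score_id,
            "n_genes": self.n_genes,
            "core_hits": self.core_hits,
            "core_fraction": self.core_fraction,
            "size_bin": self.size_bin,
            "ref_mean": self.ref_mean,
            "ref_sd": self.ref_sd,
            "z": self.z,
            "verdict": self.verdict,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def core_overlap_fraction(
    score_genes: set[str], core: CoreSet
) -> tuple[int, float]:
    """Hits = |genes ∩ core|; fraction = hits / |genes| (0 for an empty set)."""
    if not score_genes:
        logger.warning("score has no mapped genes; core fraction is 0")
        return 0, 0.0
    hits = len(set(score_genes) & core.genes)
    return hits, hits / len(score_genes)


def _size_bin(n_variants: int, bins: list[SizeStratum]) -> str | None:
    """Smallest stratum admitting the score (bins are nested)."""
    for s in sorted(bins, key=lambda s: s.threshold):
        if n_variants <= s.threshold:
            return s.label
    return None


def reference_distribution(
    reference_scores: list[tuple[str, set[str], int]],
    core: CoreSet,
    size_bins: list[SizeStratum],
) -> dict[str, ReferenceBin]:
    """Per size bin, the mean and sample sd of the core-overlap fraction.

    ``reference_scores`` are (score_id, gene set, variant count) triples;
    each score lands in the smallest bin admitting it.  At least one bin
    must hold >= 2 references.
    """
    fractions: dict[str, list[float]] = {s.label: [] for s in size_bins}
    for _, genes, size in reference_scores:
        label = _size_bin(size, size_bins)
        if label is None:
            continue
        fractions[label].append(core_overlap_fraction(genes, core)[1])
    out: dict[str, ReferenceBin] = {}
    for label, vals in fractions.items():
        n = len(vals)
        mean = sum(vals) / n if n else 0.0
        sd = (
            math.sqrt(sum((v - mean) ** 2 for v in vals) / (n - 1))
            if n >= 2
            else 0.0
        )
        out[label] = ReferenceBin(label=label, mean=mean, sd=sd, n=n)
        if n < 2:
            logger.warning("size bin %s has %d references; flagged unusable", label, n)
    if not any(b.usable for b in out.values()):
        raise ValueError("no size bin holds >= 2 reference scores")
    return out


def verify_score(
    candidate: ScoringFile,
    genemap: GeneMap,
    core: CoreSet,
    reference: dict[str, ReferenceBin],
    size_bins: list[SizeStratum],
    z_threshold: float = 2.0,
) -> VerificationReport:
    """Screen a candidate score against the reference core distribution.

    z = (fraction − ref_mean) / ref_sd for the candidate's size bin.  When
    the bin's sd is 0 the z-score is undefined: the verdict is "typical" iff
    the fraction equals the reference mean, otherwise a signed infinite
    sentinel is reported.  Verdicts: core-depleted iff z < −z_threshold,
    core-enriched iff z > +z_threshold, else typical.
    """
    bin_label = _size_bin(candidate.n_variants, size_bins)
    if bin_label is None:
        raise ValueError(
            f"candidate has {candidate.n_variants} variants, beyond every size bin"
        )
    ref = reference.get(bin_label)
    if ref is None or not ref.usable:
        raise ValueError(
            f"size bin {bin_label} lacks reference scores (need >= 2); "
            "supply more references for that bin"
        )
    genes = genemap.genes
    hits, fraction = core_overlap_fraction(genes, core)
    if ref.sd > 0:
        z = (fraction - ref.mean) / ref.sd
    else:
        z = 0.0 if fraction == ref.mean else math.copysign(math.inf, fraction - ref.mean)
    if z < -z_threshold:
        verdict = "core-depleted"
    elif z > z_threshold:
        verdict = "core-enriched"
    else:
        verdict = "typical"
    return VerificationReport(
        score_id=candidate.score_id,
        n_genes=len(genes),
        core_hits=hits,
        core_fraction=fraction,
        size_bin=bin_label,
        ref_mean=ref.mean,
        ref_sd=ref.sd,
        z=z,
        verdict=verdict,
    )
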