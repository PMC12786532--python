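"""The binary gene×disease presence matrix.

Per size stratum, every trait's scores are merged into one gene set (union
over scores) and encoded as a binary matrix: rows are diseases, columns are
genes, entry 1 means at least one of the trait's PRS variants maps to that
gene.  This matrix is the pipeline's central object — overlap statistics,
clustering and core extraction all read from it.

The same container holds SNP-level presence equally well (pass per-trait
rsID sets instead of gene sets); only the column vocabulary changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .gene_annotation import GeneMap
from .pgs_io import ScoringFile

logger = logging.getLogger(__name__)

__all__ = [
    "GenePresenceMatrix",
    "merge_trait_genes",
    "build_presence_matrix",
    "load_reference_matrix",
]


@dataclass
class GenePresenceMatrix:
    """Binary diseases×genes matrix for one size stratum.

    Rows and columns are sorted lexicographically, genes absent from every
    trait are dropped, and entries are strictly 0/1 — so two matrices built
    from the same trait→gene sets are identical regardless of input order.
    """

    stratum_label: str
    frame: pd.DataFrame  # index = diseases, columns = genes, values in {0,1}

    def __post_init__(self) -> None:
        values = self.frame.to_numpy()
        if values.size and not np.isin(values, (0, 1)).all():
            raise ValueError("presence matrix entries must be 0 or 1")
        if self.frame.index.has_duplicates or self.frame.columns.has_duplicates:
            raise ValueError("disease and gene identifiers must be unique")

    @property
    def diseases(self) -> list[str]:
        return list(self.frame.index)

    @property
    def genes(self) -> list[str]:
        return list(self.frame.columns)

    def trait_genes(self, trait: str) -> set[str]:
        """The gene set of one trait (columns with a 1 in its row)."""
        row = self.frame.loc[trait]
        return set(row.index[row == 1])

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="disease")

    @classmethod
    def from_tsv(cls, path: str | Path, stratum_label: str = "all") -> "GenePresenceMatrix":
        frame = pd.read_csv(path, sep="\t", index_col="disease")
        frame = frame.sort_index().sort_index(axis=1).astype(int)
        return cls(stratum_label=stratum_label, frame=frame)

    def to_triplets(self) -> list[tuple[str, str, int]]:
        """Sparse (disease, gene, 1) triplets in deterministic order."""
        out = []
        for disease in self.diseases:
            for gene in sorted(self.trait_genes(disease)):
                out.append((disease, gene, 1))
        return out


def merge_trait_genes(
    scores_by_trait: dict[str, list[ScoringFile]],
    genemaps: dict[str, GeneMap],
) -> tuple[dict[str, set[str]], dict[str, int]]:
    """Union each trait's mapped genes over all of its scores.

    ``genemaps`` is keyed by score id.  Also returns the per-trait unique
    variant count (union of variant keys over the trait's scores), which the
    SNP-frequency tally and logs use.
    """
    trait_genes: dict[str, set[str]] = {}
    trait_snps: dict[str, int] = {}
    for trait, scores in scores_by_trait.items():
        genes: set[str] = set()
        snps: set[str] = set()
        if not scores:
            logger.warning("trait %r has no scores; empty gene set", trait)
        for score in scores:
            gm = genemaps[score.score_id]
            genes |= gm.genes
            snps.update(gm.assignments)
            snps.update(gm.unmapped)
        trait_genes[trait] = genes
        trait_snps[trait] = len(snps)
    return trait_genes, trait_snps


def build_presence_matrix(
    trait_genes: dict[str, set[str]], stratum_label: str
) -> GenePresenceMatrix:
    """Encode trait→gene sets as a binary matrix (requires >= 2 traits)."""
    if len(trait_genes) < 2:
        raise ValueError("pairwise analysis needs at least 2 traits")
    diseases = sorted(trait_genes)
    genes = sorted(set().union(*trait_genes.values()))
    data = np.zeros((len(diseases), len(genes)), dtype=int)
    gene_index = {g: j for j, g in enumerate(genes)}
    for i, disease in enumerate(diseases):
        for gene in trait_genes[disease]:
            data[i, gene_index[gene]] = 1
    frame = pd.DataFrame(data, index=diseases, columns=genes)
    return GenePresenceMatrix(stratum_label=stratum_label, frame=frame)


def load_reference_matrix() -> GenePresenceMatrix:
    """The packaged reference of frequently shared autoimmune genes.

    A published survey of polygenic scores (at most 1000 variants each) for
    ten autoimmune diseases reported the genes most recurrently hit across
    diseases; the packaged TSV transcribes that gene→disease list.  Encoded
    here as a 10-disease presence matrix, it serves as an in-package worked
    example and test oracle.
    """
    with resources.files("prscore.data").joinpath(
        "shared_gene_reference.tsv"
    ).open() as fh:
        table = pd.read_csv(fh, sep="\t")
    trait_genes: dict[str, set[str]] = {}
    for _, row in table.iterrows():
        for disease in str(row["diseases"]).split(","):
            trait_genes.setdefault(disease.strip(), set()).add(str(row["gene"]))
    return build_presence_matrix(trait_genes, stratum_label="PRS1000")
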