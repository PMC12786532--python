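"""End-to-end glue: scores + resolvers → per-stratum presence matrices."""

from __future__ import annotations

from .core_matrix import GenePresenceMatrix, build_presence_matrix, merge_trait_genes
from .gene_annotation import GeneMap, GeneModel, annotate_score
from .pgs_io import ScoringFile, SizeStratum, assign_size_strata, default_strata

__all__ = ["annotate_collection", "stratum_matrices"]


def annotate_collection(
    scores: list[ScoringFile],
    rsid_table: dict[str, frozenset[str]] | None = None,
    model: GeneModel | None = None,
) -> dict[str, GeneMap]:
    """Annotate every score; returns gene maps keyed by score id."""
    return {
        s.score_id: annotate_score(s, rsid_table=rsid_table, model=model)
        for s in scores
    }


def stratum_matrices(
    scores: list[ScoringFile],
    genemaps: dict[str, GeneMap],
    strata: list[SizeStratum] | None = None,
) -> dict[str, GenePresenceMatrix]:
    """Per size stratum, merge each trait's admitted scores and build the
    binary presence matrix.  Traits enter a stratum only if at least one of
    their scores fits under its ceiling."""
    strata = strata if strata is not None else default_strata()
    out: dict[str, GenePresenceMatrix] = {}
    for label, files in assign_size_strata(scores, strata).items():
        by_trait: dict[str, list[ScoringFile]] = {}
        for f in files:
            if f.trait_label is None:
                raise ValueError(f"score {f.score_id} has no trait label")
            by_trait.setdefault(f.trait_label, []).append(f)
        trait_genes, _ = merge_trait_genes(by_trait, genemaps)
        out[label] = build_presence_matrix(trait_genes, stratum_label=label)
    return out
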