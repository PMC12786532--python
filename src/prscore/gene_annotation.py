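"""Offline variant→gene resolution.

Two resolvers are supported and can be combined:

* an rsID→gene table (two-column TSV, comma-separated gene lists), the
  primary route; repeated rsID rows are unioned;
* a gene-interval model loaded from BED4 (0-based, half-open), used as a
  positional fallback for variants the table does not cover.

Scoring-file positions are 1-based; the conversion to the BED convention is
centralized in :func:`annotate_score`.  Overlapping gene intervals are
legitimate (overlapping and antisense genes are real) and a variant inside
several genes contributes every symbol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from intervaltree import IntervalTree

from .pgs_io import ScoringFile

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "GeneMap",
    "load_gene_intervals",
    "load_rsid_gene_table",
    "annotate_score",
]


def _norm_chrom(chrom: str) -> str:
    """Normalize chromosome labels: a leading 'chr' is stripped."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass
class GeneModel:
    """Interval index of gene loci on one genome build."""

    build: str | None
    trees: dict[str, IntervalTree] = field(default_factory=dict)

    def add(self, chrom: str, start: int, end: int, symbol: str) -> None:
        if start >= end:
            raise ValueError(f"interval start {start} >= end {end}")
        if not symbol:
            raise ValueError("gene symbol must be nonempty")
        self.trees.setdefault(_norm_chrom(chrom), IntervalTree()).addi(
            start, end, symbol
        )

    def query(self, chrom: str, pos0: int) -> set[str]:
        """Gene symbols whose interval contains the 0-based position."""
        tree = self.trees.get(_norm_chrom(chrom))
        if tree is None:
            return set()
        return {iv.data for iv in tree.at(pos0)}

    @property
    def n_intervals(self) -> int:
        return sum(len(t) for t in self.trees.values())


@dataclass
class GeneMap:
    """Variant→genes assignment for one score.

    ``assignments`` maps each resolved variant key to its (nonempty) symbol
    set; ``unmapped`` lists the variant keys neither resolver could place.
    The two are disjoint and together cover every unique variant.
    """

    assignments: dict[str, frozenset[str]] = field(default_factory=dict)
    unmapped: list[str] = field(default_factory=list)

    @property
    def genes(self) -> set[str]:
        """Union of all assigned gene symbols."""
        out: set[str] = set()
        for symbols in self.assignments.values():
            out |= symbols
        return out

    @property
    def n_variants(self) -> int:
        return len(self.assignments) + len(self.unmapped)


def load_gene_intervals(path: str | Path, build: str | None = None) -> GeneModel:
    """Load a gene model from BED4 (chrom, start, end, name; 0-based half-open).

    Malformed rows (start >= end, missing columns) raise with the line number.
    """
    model = GeneModel(build=build)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: BED row needs >= 4 columns")
            chrom, start_s, end_s, name = parts[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from None
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            model.add(chrom, start, end, name)
    return model


def load_rsid_gene_table(path: str | Path) -> dict[str, frozenset[str]]:
    """Load an rsID→genes TSV (two columns, comma-separated gene list).

    Repeated rsID rows are unioned; rows with an empty gene field are left
    out of the mapping (logged), so their variants fall through to the
    positional resolver or end up unmapped.
    """
    table: dict[str, set[str]] = {}
    n_empty = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            rsid, _, genes_field = line.partition("\t")
            symbols = {g.strip() for g in genes_field.split(",") if g.strip()}
            if not symbols:
                n_empty += 1
                continue
            table.setdefault(rsid, set()).update(symbols)
    if n_empty:
        logger.info("%s: %d rsIDs had an empty gene field (unmapped)", path, n_empty)
    return {rsid: frozenset(sym) for rsid, sym in table.items()}


def annotate_score(
    score: ScoringFile,
    rsid_table: dict[str, frozenset[str]] | None = None,
    model: GeneModel | None = None,
) -> GeneMap:
    """Resolve every unique variant of a score to gene symbols.

    rsID lookup is tried first; variants it cannot place fall back to a
    positional interval query (1-based position converted to the 0-based
    half-open BED convention).  Variants resolved by neither route are listed
    in ``unmapped``.  The result is independent of variant order.

    Raises
    ------
    ValueError
        If no resolver is given, or the positional fallback would mix genome
        builds (both builds are named in the message).
    """
    if rsid_table is None and model is None:
        raise ValueError("at least one resolver (rsid_table or model) is required")
    if (
        model is not None
        and model.build is not None
        and score.genome_build is not None
        and model.build != score.genome_build
    ):
        raise ValueError(
            f"genome build mismatch: score is {score.genome_build}, "
            f"gene model is {model.build}"
        )

    assignments: dict[str, frozenset[str]] = {}
    unmapped: list[str] = []
    seen: set[str] = set()
    multi = 0
    for variant in score.variants:
        key = variant.key
        if key in seen:
            continue
        seen.add(key)
        symbols: frozenset[str] = frozenset()
        if rsid_table is not None and variant.rsid is not None:
            symbols = rsid_table.get(variant.rsid, frozenset())
        if not symbols and model is not None and variant.chrom is not None:
            if variant.pos is not None:
                symbols = frozenset(model.query(variant.chrom, variant.pos - 1))
        if symbols:
            assignments[key] = symbols
            if len(symbols) > 1:
                multi += 1
        else:
            unmapped.append(key)
    if multi:
        logger.info(
            "%s: %d variants map to multiple genes; all symbols kept (union rule)",
            score.score_id,
            multi,
        )
    return GeneMap(assignments=assignments, unmapped=unmapped)
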