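"""Reading PGS Catalog scoring files and organizing scores into size strata.

A *scoring file* is the PGS Catalog's distribution format for one polygenic
score: ``#key=value`` metadata lines followed by a tab-separated variant table
(rsID and/or chromosome/position, alleles, effect weight).  Only the variant
*composition* of a score is of interest here — effect weights are carried
through but never applied to genotypes.

Scores are stratified by variant count into nested size bins (e.g. at most
250, 500, 1000 variants): a score small enough for one bin belongs to every
larger bin as well.
"""

from __future__ import annotations

import gzip
import io
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VariantEntry",
    "ScoringFile",
    "PerformanceRecord",
    "SizeStratum",
    "default_strata",
    "parse_scoring_file",
    "write_scoring_file",
    "read_performance_table",
    "select_top_auc_scores",
    "assign_size_strata",
]

#: Recognized variant-table columns.  Harmonized (hm_*) coordinates are the
#: catalog's build-consistent re-annotation and take precedence over the
#: author-reported ones.
_RSID_COLS = ("hm_rsID", "rsID")
_CHR_COLS = ("hm_chr", "chr_name")
_POS_COLS = ("hm_pos", "chr_position")


@dataclass(frozen=True)
class VariantEntry:
    """One variant row of a scoring file.

    At least one of ``rsid`` or the (``chrom``, ``pos``) pair must be set;
    ``pos`` is 1-based.
    """

    rsid: str | None
    chrom: str | None
    pos: int | None
    effect_allele: str | None
    other_allele: str | None
    effect_weight: float

    def __post_init__(self) -> None:
        if self.rsid is None and (self.chrom is None or self.pos is None):
            raise ValueError("variant needs an rsid or a (chrom, pos) pair")
        if self.pos is not None and self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not math.isfinite(self.effect_weight):
            raise ValueError("effect weight must be finite")

    @property
    def key(self) -> str:
        """Stable identifier: the rsid when known, else ``chrom:pos``."""
        return self.rsid if self.rsid is not None else f"{self.chrom}:{self.pos}"


@dataclass
class ScoringFile:
    """One polygenic score: identity, trait label and its variant list."""

    score_id: str
    trait_label: str | None
    genome_build: str | None
    variants: list[VariantEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.score_id:
            raise ValueError("score_id must be nonempty")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_keys(self) -> list[str]:
        return [v.key for v in self.variants]


@dataclass(frozen=True)
class PerformanceRecord:
    """Reported predictive performance (AUC) of one score for one trait."""

    score_id: str
    trait_label: str
    auc: float

    def __post_init__(self) -> None:
        if not (0.0 < self.auc <= 1.0):
            raise ValueError(
                f"AUC for {self.score_id} must lie in (0, 1], got {self.auc}"
            )


@dataclass(frozen=True)
class SizeStratum:
    """A variant-count ceiling; membership is inclusive (count <= threshold)."""

    label: str
    threshold: int

    def __post_init__(self) -> None:
        if self.threshold < 1:
            raise ValueError("threshold must be positive")


def default_strata() -> list[SizeStratum]:
    """The conventional nested bins: at most 250, 500 and 1000 variants."""
    return [
        SizeStratum("PRS250", 250),
        SizeStratum("PRS500", 500),
        SizeStratum("PRS1000", 1000),
    ]


def _read_text(path: str | Path) -> str:
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as fh:
            return fh.read()
    return path.read_text()


def _parse_header(lines: list[str]) -> dict[str, str]:
    meta: dict[str, str] = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if "=" in body:
            key, _, value = body.partition("=")
            meta[key.strip().lower()] = value.strip()
    return meta


def _coalesce(row: pd.Series, columns: tuple[str, ...]) -> str | None:
    """First non-null value across ``columns`` (harmonized first)."""
    for col in columns:
        if col in row.index and pd.notna(row[col]) and str(row[col]) != "":
            return str(row[col])
    return None


def parse_scoring_file(
    path: str | Path, trait_label: str | None = None
) -> ScoringFile:
    """Parse one PGS Catalog scoring file (plain or gzip).

    Harmonized columns (``hm_rsID``/``hm_chr``/``hm_pos``) outrank the
    author-reported ones.  ``score_id`` and the trait label come from the
    ``#pgs_id=`` / ``#trait_reported=`` header lines when present, falling
    back to the file name and the ``trait_label`` argument.  Duplicate rsIDs
    are collapsed to their first occurrence (logged).

    Raises
    ------
    ValueError
        If the file has no variant rows, lacks both rsID and positional
        columns, or an effect weight fails to parse (the offending row index
        is named).
    """
    path = Path(path)
    text = _read_text(path)
    lines = text.splitlines()
    meta = _parse_header([ln for ln in lines if ln.startswith("#")])
    body = "\n".join(ln for ln in lines if not ln.startswith("#") and ln.strip())
    if not body:
        raise ValueError(f"{path}: scoring file has no data section")

    table = pd.read_csv(io.StringIO(body), sep="\t", dtype=str)
    if table.empty:
        raise ValueError(f"{path}: scoring file has no variant rows")

    has_rsid = any(c in table.columns for c in _RSID_COLS)
    has_pos = any(c in table.columns for c in _CHR_COLS) and any(
        c in table.columns for c in _POS_COLS
    )
    if not has_rsid and not has_pos:
        raise ValueError(
            f"{path}: no rsID column and no chromosome/position columns found"
        )
    if "effect_weight" not in table.columns:
        raise ValueError(f"{path}: missing effect_weight column")

    score_id = meta.get("pgs_id") or re.sub(r"\.(txt|tsv)(\.gz)?$", "", path.name)
    trait = (
        meta.get("trait_reported")
        or meta.get("trait_mapped")
        or meta.get("trait")
        or trait_label
    )
    build = meta.get("hmpos_build") or meta.get("genome_build")

    variants: list[VariantEntry] = []
    seen_rsids: set[str] = set()
    n_dup = 0
    for idx, row in table.iterrows():
        raw_weight = row.get("effect_weight")
        try:
            weight = float(raw_weight)
        except (TypeError, ValueError):
            raise ValueError(
                f"{path}: non-numeric effect_weight {raw_weight!r} at data row {idx}"
            ) from None
        rsid = _coalesce(row, _RSID_COLS)
        chrom = _coalesce(row, _CHR_COLS)
        pos_raw = _coalesce(row, _POS_COLS)
        pos = int(float(pos_raw)) if pos_raw is not None else None
        if rsid is not None:
            if rsid in seen_rsids:
                n_dup += 1
                continue
            seen_rsids.add(rsid)
        variants.append(
            VariantEntry(
                rsid=rsid,
                chrom=chrom,
                pos=pos,
                effect_allele=_coalesce(row, ("effect_allele",)),
                other_allele=_coalesce(row, ("other_allele",)),
                effect_weight=weight,
            )
        )
    if n_dup:
        logger.info("%s: collapsed %d duplicate rsID rows", path.name, n_dup)
    return ScoringFile(
        score_id=score_id, trait_label=trait, genome_build=build, variants=variants
    )


def write_scoring_file(score: ScoringFile, path: str | Path) -> None:
    """Write a score back to the scoring-file dialect (round-trip safe)."""
    path = Path(path)
    rows = []
    for v in score.variants:
        rows.append(
            {
                "rsID": v.rsid if v.rsid is not None else "",
                "chr_name": v.chrom if v.chrom is not None else "",
                "chr_position": v.pos if v.pos is not None else "",
                "effect_allele": v.effect_allele or "",
                "other_allele": v.other_allele or "",
                "effect_weight": repr(v.effect_weight),
            }
        )
    header = [f"#pgs_id={score.score_id}"]
    if score.trait_label:
        header.append(f"#trait_reported={score.trait_label}")
    if score.genome_build:
        header.append(f"#genome_build={score.genome_build}")
    frame = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_performance_table(path: str | Path) -> list[PerformanceRecord]:
    """Read a score→trait→AUC table (CSV or TSV, sniffed).

    Rows with a missing AUC are skipped and counted in the log; an AUC
    outside (0, 1] raises.
    """
    table = pd.read_csv(path, sep=None, engine="python")
    required = {"score_id", "trait", "auc"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records: list[PerformanceRecord] = []
    n_skipped = 0
    for _, row in table.iterrows():
        if pd.isna(row["auc"]):
            n_skipped += 1
            continue
        records.append(
            PerformanceRecord(
                score_id=str(row["score_id"]),
                trait_label=str(row["trait"]),
                auc=float(row["auc"]),
            )
        )
    if n_skipped:
        logger.info("%s: skipped %d rows with missing AUC", path, n_skipped)
    if not records:
        raise ValueError(f"{path}: no parseable performance rows")
    return records


def select_top_auc_scores(
    records: list[PerformanceRecord], k: int
) -> dict[str, list[str]]:
    """Per trait, the ``k`` score ids with the highest AUC.

    AUC ties are broken by ascending score id so the selection is
    reproducible; traits with fewer than ``k`` scores return all of them.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    by_trait: dict[str, list[PerformanceRecord]] = {}
    for rec in records:
        by_trait.setdefault(rec.trait_label, []).append(rec)
    out: dict[str, list[str]] = {}
    for trait, recs in by_trait.items():
        ranked = sorted(recs, key=lambda r: (-r.auc, r.score_id))
        out[trait] = [r.score_id for r in ranked[:k]]
    return out


def assign_size_strata(
    files: list[ScoringFile], strata: list[SizeStratum]
) -> dict[str, list[ScoringFile]]:
    """Assign each score to every stratum whose ceiling admits it.

    Ceilings are inclusive (a 250-variant score belongs to the 250 bin), and
    because thresholds are strictly increasing the bins are nested: anything
    in a smaller bin is in every larger one.
    """
    thresholds = [s.threshold for s in strata]
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("stratum thresholds must be strictly increasing")
    out: dict[str, list[ScoringFile]] = {s.label: [] for s in strata}
    for f in files:
        for s in strata:
            if f.n_variants <= s.threshold:
                out[s.label].append(f)
    return out
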