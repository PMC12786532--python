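"""Synthetic scoring-file cohorts with known ground truth.

Real collections of polygenic scores cannot be redistributed and their gene
annotation needs live database access, so every pipeline stage is exercised
on generated cohorts instead.  The generator emulates the statistical
structure the analysis is built to detect:

* ~10 traits organized into latent clusters, each cluster sharing a planted
  "core" of genes, plus unclustered singleton traits;
* trait-specific padding genes disjoint across traits, so planted
  between-cluster sharing is exactly zero unless a global core is requested;
* nested size strata — each trait's smaller scoring file is a strict subset
  of its larger ones, with the full cluster core planted in the smallest
  file (core recovery is then exact, only the padding is stochastic);
* a matching gene-interval BED and rsID→gene TSV, so annotation can be
  verified as a round trip.

It does not model LD, allele frequencies or genotypes — only variant/gene
composition, which is all the downstream analysis reads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .gene_annotation import GeneModel
from .pgs_io import (
    PerformanceRecord,
    ScoringFile,
    SizeStratum,
    VariantEntry,
    default_strata,
    write_scoring_file,
)

__all__ = [
    "SyntheticSNP",
    "GeneUniverse",
    "SyntheticTruth",
    "Cohort",
    "generate_gene_universe",
    "default_truth",
    "generate_scoring_collection",
    "default_cohort",
    "scoring_file_from_genes",
    "write_cohort",
]

_ALLELES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SyntheticSNP:
    rsid: str
    chrom: str
    pos: int  # 1-based
    gene: str


@dataclass
class GeneUniverse:
    """Synthetic gene loci plus their SNP pools and offline resolvers."""

    build: str
    model: GeneModel
    rsid_table: dict[str, frozenset[str]]
    gene_snps: dict[str, list[SyntheticSNP]]
    intervals: list[tuple[str, int, int, str]]  # chrom, start0, end0, gene

    @property
    def genes(self) -> list[str]:
        return list(self.gene_snps)

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end, gene in self.intervals:
                fh.write(f"{chrom}\t{start}\t{end}\t{gene}\n")

    def write_rsid_table(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for gene, snps in self.gene_snps.items():
                for snp in snps:
                    fh.write(f"{snp.rsid}\t{gene}\n")


def generate_gene_universe(
    n_genes: int,
    genome_span: int = 120_000_000,
    seed: int = 0,
    snps_per_gene: tuple[int, int] = (9, 11),
    build: str = "GRCh38",
    gene_length: int = 20_000,
) -> GeneUniverse:
    """Place ``n_genes`` disjoint gene intervals on synthetic chromosomes.

    Genes are distributed round-robin over 22 chromosomes of ``genome_span``
    bases each and laid out left to right with random gaps; each gene gets a
    pool of SNPs (count uniform in ``snps_per_gene``) at distinct positions
    inside its interval, with deterministic sequential rsIDs.  Identical
    seeds reproduce the universe exactly.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = snps_per_gene
    if not (1 <= lo <= hi):
        raise ValueError("invalid snps_per_gene range")
    rng = np.random.default_rng(seed)
    chroms = [str(c) for c in range(1, 23)]
    cursor = {c: 0 for c in chroms}
    model = GeneModel(build=build)
    intervals: list[tuple[str, int, int, str]] = []
    gene_snps: dict[str, list[SyntheticSNP]] = {}
    rsid_table: dict[str, frozenset[str]] = {}
    rs_counter = 1_000_000
    for i in range(n_genes):
        gene = f"GENE{i:04d}"
        chrom = chroms[i % len(chroms)]
        gap = int(rng.integers(5_000, 50_000))
        start = cursor[chrom] + gap
        end = start + gene_length
        if end > genome_span:
            raise ValueError(
                f"genome span {genome_span} too small to place {n_genes} genes"
            )
        cursor[chrom] = end
        model.add(chrom, start, end, gene)
        intervals.append((chrom, start, end, gene))
        n_snps = int(rng.integers(lo, hi + 1))
        offsets = rng.choice(gene_length, size=n_snps, replace=False)
        snps = []
        for off in sorted(int(o) for o in offsets):
            rsid = f"rs{rs_counter}"
            rs_counter += 1
            snps.append(SyntheticSNP(rsid=rsid, chrom=chrom, pos=start + off + 1, gene=gene))
            rsid_table[rsid] = frozenset({gene})
        gene_snps[gene] = snps
    return GeneUniverse(
        build=build,
        model=model,
        rsid_table=rsid_table,
        gene_snps=gene_snps,
        intervals=intervals,
    )


@dataclass
class SyntheticTruth:
    """Ground-truth record of what a cohort was built to contain."""

    seed: int
    cluster_labels: dict[str, int]  # every trait, singletons included
    core_genes: dict[int, frozenset[str]]  # multi-trait clusters only
    global_core: frozenset[str]
    specific_genes: dict[str, frozenset[str]]
    snps_per_gene: tuple[int, int]
    strata_sizes: list[int]  # per-trait file sizes, one per stratum
    strata: list[SizeStratum] = field(default_factory=default_strata)

    def __post_init__(self) -> None:
        cores = list(self.core_genes.values())
        for i in range(len(cores)):
            for j in range(i + 1, len(cores)):
                if cores[i] & cores[j]:
                    raise ValueError("per-cluster cores must be pairwise disjoint")
        all_core = frozenset().union(self.global_core, *cores) if cores else self.global_core
        for trait, spec in self.specific_genes.items():
            if spec & all_core:
                raise ValueError(f"specific genes of {trait} intersect a core")
        for size, stratum in zip(self.strata_sizes, self.strata):
            if size > stratum.threshold:
                raise ValueError(
                    f"file size {size} exceeds stratum ceiling {stratum.threshold}"
                )

    @property
    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for trait, cid in self.cluster_labels.items():
            out.setdefault(cid, []).append(trait)
        return {cid: sorted(ts) for cid, ts in sorted(out.items())}

    @property
    def multi_clusters(self) -> dict[int, list[str]]:
        return {cid: ts for cid, ts in self.clusters.items() if len(ts) >= 2}

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "cluster_labels": self.cluster_labels,
            "core_genes": {str(c): sorted(g) for c, g in self.core_genes.items()},
            "global_core": sorted(self.global_core),
            "specific_genes": {t: sorted(g) for t, g in self.specific_genes.items()},
            "snps_per_gene": list(self.snps_per_gene),
            "strata_sizes": self.strata_sizes,
            "strata": [[s.label, s.threshold] for s in self.strata],
        }


def default_truth(
    universe: GeneUniverse,
    seed: int,
    cluster_sizes: tuple[int, ...] = (2, 3, 2),
    n_unclustered: int = 3,
    core_size: int = 14,
    n_global_core: int = 0,
    strata_sizes: tuple[int, ...] = (240, 480, 960),
    specific_pool_clustered: int = 100,
    specific_pool_unclustered: int = 115,
) -> SyntheticTruth:
    """Plan the default cohort: 10 traits, clusters of 2/3/2 plus 3
    singletons, nested file sizes 240/480/960 under ceilings 250/500/1000.

    Gene roles (cluster cores, optional global core, per-trait specific
    pools) are drawn disjointly from the universe with the given seed.
    """
    rng = np.random.default_rng(seed)
    genes = list(universe.genes)
    perm = [genes[i] for i in rng.permutation(len(genes))]
    n_clustered = sum(cluster_sizes)
    n_traits = n_clustered + n_unclustered
    traits = [f"trait_{i + 1:02d}" for i in range(n_traits)]

    need = (
        n_global_core
        + core_size * len(cluster_sizes)
        + specific_pool_clustered * n_clustered
        + specific_pool_unclustered * n_unclustered
    )
    if need > len(perm):
        raise ValueError(
            f"universe has {len(perm)} genes but the plan needs {need}"
        )
    it = iter(perm)

    def take(n: int) -> frozenset[str]:
        return frozenset(next(it) for _ in range(n))

    global_core = take(n_global_core)
    cluster_labels: dict[str, int] = {}
    core_genes: dict[int, frozenset[str]] = {}
    ti = 0
    for cid, size in enumerate(cluster_sizes, start=1):
        core_genes[cid] = take(core_size)
        for _ in range(size):
            cluster_labels[traits[ti]] = cid
            ti += 1
    next_cid = len(cluster_sizes) + 1
    for _ in range(n_unclustered):
        cluster_labels[traits[ti]] = next_cid
        ti += 1
        next_cid += 1

    specific: dict[str, frozenset[str]] = {}
    for trait in traits:
        pool = (
            specific_pool_clustered
            if len([t for t, c in cluster_labels.items() if c == cluster_labels[trait]]) >= 2
            else specific_pool_unclustered
        )
        specific[trait] = take(pool)

    return SyntheticTruth(
        seed=seed,
        cluster_labels=cluster_labels,
        core_genes=core_genes,
        global_core=global_core,
        specific_genes=specific,
        snps_per_gene=(9, 11),
        strata_sizes=list(strata_sizes),
    )


def _variant_from_snp(snp: SyntheticSNP, rng: np.random.Generator) -> VariantEntry:
    ea, oa = rng.choice(4, size=2, replace=False)
    return VariantEntry(
        rsid=snp.rsid,
        chrom=snp.chrom,
        pos=snp.pos,
        effect_allele=str(_ALLELES[ea]),
        other_allele=str(_ALLELES[oa]),
        effect_weight=float(rng.standard_normal()),
    )


def generate_scoring_collection(
    truth: SyntheticTruth, universe: GeneUniverse
) -> tuple[list[ScoringFile], list[PerformanceRecord]]:
    """Emit one scoring file per trait per stratum, nested by construction.

    The smallest file carries *every* SNP of the trait's cluster core (and
    of the global core), then trait-specific genes' SNPs up to the stratum's
    target size; larger files extend the same variant list with further
    specific SNPs.  Effect weights ~ N(0, 1); per-file AUC ~ U(0.5, 0.95).
    """
    rng = np.random.default_rng(truth.seed + 1)
    scores: list[ScoringFile] = []
    performance: list[PerformanceRecord] = []
    idx = 0
    for trait in sorted(truth.cluster_labels):
        cid = truth.cluster_labels[trait]
        core = truth.core_genes.get(cid, frozenset()) | truth.global_core
        core_snps = [
            snp for gene in sorted(core) for snp in universe.gene_snps[gene]
        ]
        spec = sorted(truth.specific_genes[trait])
        order = rng.permutation(len(spec))
        stream = [
            snp for i in order for snp in universe.gene_snps[spec[i]]
        ]
        if truth.strata_sizes[0] < len(core_snps):
            raise ValueError(
                f"{trait}: smallest stratum size {truth.strata_sizes[0]} cannot "
                f"hold the {len(core_snps)} planted core SNPs"
            )
        if max(truth.strata_sizes) > len(core_snps) + len(stream):
            raise ValueError(
                f"{trait}: requested size {max(truth.strata_sizes)} exceeds the "
                f"available SNP pool ({len(core_snps) + len(stream)})"
            )
        for size, stratum in zip(truth.strata_sizes, truth.strata):
            snps = core_snps + stream[: size - len(core_snps)]
            idx += 1
            score_id = f"PGS9{idx:05d}"
            variants = [_variant_from_snp(s, rng) for s in snps]
            scores.append(
                ScoringFile(
                    score_id=score_id,
                    trait_label=trait,
                    genome_build=universe.build,
                    variants=variants,
                )
            )
            performance.append(
                PerformanceRecord(
                    score_id=score_id,
                    trait_label=trait,
                    auc=float(rng.uniform(0.5, 0.95)),
                )
            )
    return scores, performance


@dataclass
class Cohort:
    """A fully generated study: files, metadata, resolvers, ground truth."""

    universe: GeneUniverse
    truth: SyntheticTruth
    scores: list[ScoringFile]
    performance: list[PerformanceRecord]


def default_cohort(seed: int, n_genes: int = 1150, **truth_kwargs) -> Cohort:
    """Generate the default 10-trait, 3-cluster cohort from one seed."""
    universe = generate_gene_universe(n_genes=n_genes, seed=seed)
    truth = default_truth(universe, seed=seed, **truth_kwargs)
    scores, performance = generate_scoring_collection(truth, universe)
    return Cohort(universe=universe, truth=truth, scores=scores, performance=performance)


def scoring_file_from_genes(
    universe: GeneUniverse,
    genes: list[str],
    score_id: str,
    trait_label: str,
    rng: np.random.Generator,
    n_variants: int | None = None,
) -> ScoringFile:
    """Build a candidate score from chosen genes (one SNP per gene by
    default, more when ``n_variants`` asks for them)."""
    stream = [snp for gene in genes for snp in universe.gene_snps[gene]]
    if n_variants is None:
        snps = [universe.gene_snps[g][0] for g in genes]
    else:
        if n_variants > len(stream):
            raise ValueError("requested more variants than the genes provide")
        snps = stream[:n_variants]
    return ScoringFile(
        score_id=score_id,
        trait_label=trait_label,
        genome_build=universe.build,
        variants=[_variant_from_snp(s, rng) for s in snps],
    )


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Materialize a cohort on disk: scoring files, BED, rsID TSV,
    performance CSV and the ground-truth JSON.  Deterministic per seed."""
    outdir = Path(outdir)
    (outdir / "scores").mkdir(parents=True, exist_ok=True)
    for score in cohort.scores:
        write_scoring_file(score, outdir / "scores" / f"{score.score_id}.txt")
    cohort.universe.write_bed(outdir / "genes.bed")
    cohort.universe.write_rsid_table(outdir / "rsid_map.tsv")
    with open(outdir / "performance.csv", "w") as fh:
        fh.write("score_id,trait,auc\n")
        for rec in cohort.performance:
            fh.write(f"{rec.score_id},{rec.trait_label},{rec.auc!r}\n")
    (outdir / "truth.json").write_text(
        json.dumps(cohort.truth.to_dict(), indent=2) + "\n"
    )
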