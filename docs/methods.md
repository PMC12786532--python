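# Methods

## Scope and model of the data

`prscore` treats a polygenic score purely as a *composition*: the set of
variants it lists and, after annotation, the set of genes those variants
fall in. Effect weights are parsed and preserved (round-trip I/O) but never
applied to genotypes; nothing in the package estimates risk. The analysis
object is the binary presence matrix M (diseases × genes) per size stratum,
with entry 1 iff at least one variant of at least one of the disease's
scores maps to that gene. Genes absent from every disease are dropped and
rows/columns are sorted lexicographically, so M is a pure function of the
per-disease gene sets.

## Size strata

Scores are binned by variant count under inclusive ceilings (default 250,
500, 1000). Inclusive was chosen because published descriptions of such
stratifications use "fewer than" and "up to" interchangeably; the ceilings
are configurable, and the choice only moves boundary cases. Because a score
under a small ceiling is under every larger one, strata are nested, and
union-merging per disease makes the per-disease gene sets nested across
strata as well. This nesting is asserted end-to-end in the tests rather
than assumed.

## Annotation

Variant→gene resolution is strictly offline for reproducibility: an
rsID→gene TSV is consulted first, then a BED4 interval model as positional
fallback (1-based scoring-file positions converted centrally to the
0-based half-open BED convention; chromosome labels matched after
stripping a leading `chr`). Live database lookups are deliberately out of
scope. A variant inside several (overlapping or antisense) genes keeps
every symbol — antisense and readthrough transcripts are distinct genes
and are never merged. Variants neither resolver can place contribute
nothing; they are counted and reported, not imputed.

## Sharing statistics and cores

For each unordered disease pair the package reports the shared count, the
union size, Jaccard J = |A∩B|/|A∪B| and the overlap coefficient
|A∩B|/min(|A|,|B|). The "mean common-gene fraction" of a matrix is the
arithmetic mean over pairs of one of these, ×100; Jaccard is the default
denominator convention and the overlap coefficient is available because
the choice is genuinely open for this kind of summary, and the two diverge
when set sizes are unbalanced. Degenerate cases are pinned: J = 0 for an
empty union, overlap coefficient 0 when either set is empty.

Core sets are defined by explicit rules and always stored with the rule
that produced them, so any core can be re-derived from its source matrix:

* frequency core — genes present in ≥ m diseases (ties in the frequency
  ranking break lexicographically);
* cluster core — intersection of the member diseases' gene sets;
* cross-stratum core — intersection of one cluster's cores across strata
  (with nested strata this provably equals the smallest stratum's core,
  which the tests verify by brute force);
* between-cluster core — intersection across cluster cores.

## Clustering

All geometry uses the precomputed Jaccard distance 1 − J. The t-SNE
embedding (scikit-learn, `metric="precomputed"`, random init, fixed seed,
default perplexity 3) is for visualization; cluster membership is assigned
by average-linkage agglomerative clustering on the same distances, cut at
k, because eyeballing an embedding is not reproducible. Traits are sorted
before linkage so merge ties resolve deterministically, and cluster ids
are renumbered contiguously from 1. For small panels the common
n > 3·perplexity rule cannot hold; the embedding accepts any n ≥ 3 and
caps perplexity at (n−1)/3 with a warning. Partition agreement across
strata is quantified by the adjusted Rand index (chance-corrected; 1 means
identical partitions).

## Verification of a candidate score

The screening statistic is the candidate's core-overlap fraction
f = |genes ∩ core|/|genes| compared against size-matched references:
references are binned by the same strata (each score in the smallest bin
admitting it), and each usable bin (≥ 2 references) contributes a mean and
sample standard deviation. z = (f − μ)/σ; with σ = 0 the z-score is
undefined and the report carries a signed infinite sentinel unless f
equals μ exactly. The default flag threshold |z| > 2 is a conventional
choice, exposed as a parameter, and the report always carries the raw
fraction so downstream users can apply their own rule. Size-binning
matters because the expected core fraction falls as scores grow. The
verdict is a plausibility screen only — no clinical claim.

## Synthetic cohorts

The generator emulates the structure the pipeline is designed to detect,
with all randomness flowing from a single seed:

* **Gene universe** — disjoint 20 kb gene intervals placed with random
  gaps across 22 synthetic chromosomes; each gene carries 9–11 SNPs at
  distinct positions with sequential rsIDs. The emitted BED and rsID TSV
  are mutually consistent, so annotation is tested as an exact round trip.
* **Default cohort** — 10 traits: clusters of sizes 2, 3 and 2 plus 3
  singleton traits; one scoring file per trait per stratum with sizes
  240/480/960 under ceilings 250/500/1000, built as strict nested subsets.
* **Planted structure** — each real cluster has a 14-gene core whose SNPs
  are all present already in the smallest file (cores are planted
  deterministically so recovery assertions can be exact); padding genes
  are trait-specific and disjoint across traits, so planted
  between-cluster sharing is exactly zero unless a global core is
  explicitly requested. With these sizes the within-cluster Jaccard at the
  smallest stratum is ≈ 0.33–0.40 and between-cluster sharing is 0, which
  is the regime where exact cluster recovery is a fair demand.
* **Noise** — effect weights N(0, 1); per-score AUC uniform(0.5, 0.95)
  (used only to exercise top-k selection).

What the generator does *not* emulate: linkage disequilibrium (real shared
signals, especially in the MHC, are regionally correlated), allele
frequencies, genotypes, overlapping gene models in the universe (the
annotator supports them; the generator keeps intervals disjoint so the
round-trip oracle is exact), and partially overlapping cluster cores.
Passing tests therefore demonstrate correctness of the set algebra,
clustering and screening machinery under clean planted signal — not that
real catalog data will show equally crisp clusters.

## Numerical and testing choices

Deterministic tie-breaks everywhere (lexicographic gene/trait ordering,
score-id tie-break in top-AUC selection); duplicate rsIDs within a file
collapse to the first occurrence with a logged count; AUC validated into
(0, 1]. Test oracles are independent nested-loop set-algebra
recomputations over plain lists, never calls back into the package, and
statistical checks (ARI of random partitions near 0, reference-mean
convergence to the sampling probability) use seeded Monte Carlo with error
bounds derived from the binomial variance. The acceptance script's problem
sizes — one default cohort, 30 reference scores per distribution, 20
paired verification draws — are the package's standard demonstration
sizes and complete in seconds.
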