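import numpy as np
import pytest

from prscore.core_matrix import build_presence_matrix
from prscore.overlap_stats import (
    CoreSet,
    between_cluster_common,
    cluster_core_genes,
    cross_stratum_core,
    gene_disease_frequency,
    mean_pairwise_fraction,
    pairwise_overlap,
    select_shared_core,
)

from oracles import (
    brute_core_by_frequency,
    brute_frequency_ranking,
    brute_intersection,
    brute_pair_stats,
)


def _matrix(sets, label="s"):
    return build_presence_matrix(sets, label)


def random_trait_sets(rng, max_traits=6, max_genes=30):
    n_traits = int(rng.integers(2, max_traits + 1))
    n_genes = int(rng.integers(2, max_genes + 1))
    genes = [f"g{j}" for j in range(n_genes)]
    sets = {}
    for i in range(n_traits):
        mask = rng.random(n_genes) < rng.uniform(0.1, 0.8)
        chosen = {g for g, m in zip(genes, mask) if m}
        if not chosen:
            chosen = {genes[int(rng.integers(n_genes))]}
        sets[f"t{i}"] = chosen
    return sets


class TestPairwiseOverlap:
    def test_worked_example(self):
        mat = _matrix({"A": {"g1", "g2", "g3"}, "B": {"g2", "g3", "g4"}})
        (res,) = pairwise_overlap(mat)
        assert (res.n_shared, res.n_union) == (2, 4)
        assert res.jaccard == 0.5
        assert res.overlap_coef == pytest.approx(2 / 3)
        assert res.shared_genes == {"g2", "g3"}

    def test_identical_sets(self):
        mat = _matrix({"A": {"g1", "g2"}, "B": {"g1", "g2"}})
        (res,) = pairwise_overlap(mat)
        assert res.jaccard == res.overlap_coef == 1.0

    def test_bounds_symmetry_and_ordering(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            sets = random_trait_sets(rng)
            results = pairwise_overlap(_matrix(sets))
            for r in results:
                assert r.pair[0] < r.pair[1]
                assert 0 <= r.jaccard <= r.overlap_coef <= 1
                assert r.n_shared <= r.n_union

    def test_matches_brute_force(self):
        rng = np.random.default_rng(17)
        sets = random_trait_sets(rng)
        results = {r.pair: r for r in pairwise_overlap(_matrix(sets))}
        for pair, r in results.items():
            ns, nu, jac, ov, shared = brute_pair_stats(sets[pair[0]], sets[pair[1]])
            assert (r.n_shared, r.n_union) == (ns, nu)
            assert r.jaccard == pytest.approx(jac)
            assert r.overlap_coef == pytest.approx(ov)
            assert set(r.shared_genes) == shared


class TestMeanPairwiseFraction:
    def test_simple_average(self):
        mat = _matrix({"A": {"g1"}, "B": {"g1", "g2", "g3", "g4", "g5",
                                          "g6", "g7", "g8", "g9", "g10"}})
        (res,) = pairwise_overlap(mat)
        assert mean_pairwise_fraction([res]) == pytest.approx(100 * res.jaccard)

    def test_two_pair_mean(self):
        r1 = pairwise_overlap(_matrix({"A": {"g1"}, "B": {"g1"} | {f"x{i}" for i in range(9)}}))[0]
        assert r1.jaccard == pytest.approx(0.1)
        r2 = pairwise_overlap(_matrix({"A": {"g1", "g2", "g3"}, "B": {"g1", "g2", "g3", "x1", "x2",
                                                                      "x3", "x4", "x5", "x6", "x7"}}))[0]
        assert r2.jaccard == pytest.approx(0.3)
        assert mean_pairwise_fraction([r1, r2]) == pytest.approx(20.0)

    def test_all_identical_traits_is_100(self):
        mat = _matrix({t: {"g1", "g2"} for t in "ABC"})
        assert mean_pairwise_fraction(pairwise_overlap(mat)) == 100.0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            mean_pairwise_fraction([])

    def test_unknown_fraction_raises(self):
        mat = _matrix({"A": {"g"}, "B": {"g"}})
        with pytest.raises(ValueError):
            mean_pairwise_fraction(pairwise_overlap(mat), fraction="dice")


class TestFrequencyAndCores:
    def test_reference_top_gene(self, reference_matrix):
        gene, count = gene_disease_frequency(reference_matrix)[0]
        assert (gene, count) == ("TSBP1-AS1", 8)

    def test_single_ubiquitous_gene_ranks_first(self):
        mat = _matrix({"A": {"u", "a"}, "B": {"u"}, "C": {"u", "c"}})
        assert gene_disease_frequency(mat)[0] == ("u", 3)

    def test_ties_broken_lexicographically(self):
        mat = _matrix({"A": {"b", "a"}, "B": {"b", "a"}})
        assert gene_disease_frequency(mat) == [("a", 2), ("b", 2)]

    def test_shared_core_min8_on_reference(self, reference_matrix):
        core = select_shared_core(reference_matrix, min_count=8)
        assert core.genes == {"TSBP1-AS1"}

    def test_min_count_1_returns_all(self, reference_matrix):
        core = select_shared_core(reference_matrix, min_count=1)
        assert core.genes == set(reference_matrix.genes)

    def test_min_count_out_of_range(self, reference_matrix):
        with pytest.raises(ValueError):
            select_shared_core(reference_matrix, min_count=11)

    def test_cluster_core_small_example(self):
        mat = _matrix({"X": {"A", "B"}, "Y": {"B", "C"}})
        assert cluster_core_genes(mat, {"X", "Y"}).genes == {"B"}

    def test_cluster_core_identical_traits(self):
        mat = _matrix({"X": {"A", "B"}, "Y": {"A", "B"}})
        assert cluster_core_genes(mat, {"X", "Y"}).genes == {"A", "B"}

    def test_cluster_core_unknown_trait(self):
        mat = _matrix({"X": {"A"}, "Y": {"A"}})
        with pytest.raises(ValueError, match="unknown"):
            cluster_core_genes(mat, {"X", "Zzz"})

    def test_cross_stratum_core(self):
        c1 = CoreSet("cluster:X+Y", frozenset("ABC"), "r", "PRS250")
        c2 = CoreSet("cluster:X+Y", frozenset("BCD"), "r", "PRS500")
        assert cross_stratum_core([c1, c2]).genes == {"B", "C"}

    def test_cross_stratum_identity(self):
        c = CoreSet("cluster:X+Y", frozenset("AB"), "r", "PRS250")
        assert cross_stratum_core([c, c]).genes == c.genes

    def test_cross_stratum_rejects_mixed_clusters(self):
        c1 = CoreSet("cluster:X+Y", frozenset("A"), "r", "PRS250")
        c2 = CoreSet("cluster:P+Q", frozenset("A"), "r", "PRS500")
        with pytest.raises(ValueError):
            cross_stratum_core([c1, c2])

    def test_between_cluster_disjoint_is_empty(self):
        cores = [
            CoreSet("cluster:a", frozenset("AB"), "r"),
            CoreSet("cluster:b", frozenset("CD"), "r"),
        ]
        assert between_cluster_common(cores).genes == frozenset()

    def test_between_cluster_single_removal_empties(self):
        cores = [
            CoreSet("cluster:a", frozenset({"S", "A"}), "r"),
            CoreSet("cluster:b", frozenset({"S", "B"}), "r"),
            CoreSet("cluster:c", frozenset({"C"}), "r"),
        ]
        assert between_cluster_common(cores).genes == frozenset()

    def test_core_json_round_trip(self, tmp_path):
        core = CoreSet("cluster:X+Y", frozenset("AB"), "rule text", "PRS250")
        path = tmp_path / "core.json"
        core.to_json(path)
        assert CoreSet.from_json(path) == core


class TestBruteForceEquivalence:
    """Every statistic equals a nested-loop recomputation from raw sets."""

    @pytest.mark.parametrize("seed", range(10))
    def test_random_matrix_agreement(self, seed):
        rng = np.random.default_rng(1000 + seed)
        sets = random_trait_sets(rng)
        mat = _matrix(sets)
        ranking = gene_disease_frequency(mat)
        assert ranking == brute_frequency_ranking(sets)
        min_count = int(rng.integers(1, len(sets) + 1))
        core = select_shared_core(mat, min_count)
        assert core.genes == brute_core_by_frequency(sets, min_count)
        traits = sorted(sets)
        cluster = set(traits[:2])
        assert cluster_core_genes(mat, cluster).genes == brute_intersection(
            [sets[t] for t in sorted(cluster)]
        )


class TestPlantedCohort:
    def test_cluster_cores_recovered(self, cohort, cohort_matrices):
        truth = cohort.truth
        for mat in cohort_matrices.values():
            for cid, members in truth.multi_clusters.items():
                core = cluster_core_genes(mat, set(members))
                assert core.genes == truth.core_genes[cid]

    def test_cross_stratum_equals_smallest_stratum_core(self, cohort, cohort_matrices):
        truth = cohort.truth
        order = ["PRS250", "PRS500", "PRS1000"]
        for cid, members in truth.multi_clusters.items():
            cores = [
                cluster_core_genes(cohort_matrices[lab], set(members))
                for lab in order
            ]
            assert cross_stratum_core(cores).genes == cores[0].genes

    def test_between_cluster_common_empty(self, cohort, cohort_matrices):
        truth = cohort.truth
        for mat in cohort_matrices.values():
            cores = [
                cluster_core_genes(mat, set(m))
                for m in truth.multi_clusters.values()
            ]
            assert between_cluster_common(cores).genes == frozenset()

    def test_mean_fraction_matches_raw_set_recomputation(self, cohort_matrices):
        mat = cohort_matrices["PRS250"]
        sets = {t: mat.trait_genes(t) for t in mat.diseases}
        results = pairwise_overlap(mat)
        total, n = 0.0, 0
        for i, a in enumerate(sorted(sets)):
            for b in sorted(sets)[i + 1:]:
                total += brute_pair_stats(sets[a], sets[b])[2]
                n += 1
        assert mean_pairwise_fraction(results) == pytest.approx(100 * total / n)
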