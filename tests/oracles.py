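"""Independent nested-loop set-algebra oracles.

Deliberately naive: everything is recomputed with explicit loops over plain
lists, never by calling the package under test, so agreement is a genuine
cross-check rather than a tautology.
"""


def brute_shared(a, b):
    return [g for g in sorted(a) if g in b]


def brute_union(a, b):
    out = list(sorted(a))
    for g in sorted(b):
        if g not in out:
            out.append(g)
    return out


def brute_pair_stats(a, b):
    shared = brute_shared(a, b)
    union = brute_union(a, b)
    n_shared, n_union = len(shared), len(union)
    jac = n_shared / n_union if n_union else 0.0
    smaller = min(len(list(a)), len(list(b)))
    ov = n_shared / smaller if smaller else 0.0
    return n_shared, n_union, jac, ov, set(shared)


def brute_gene_counts(trait_genes):
    """gene → number of traits carrying it, by scanning every trait."""
    counts = {}
    for _, genes in trait_genes.items():
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    return counts


def brute_frequency_ranking(trait_genes):
    counts = brute_gene_counts(trait_genes)
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def brute_core_by_frequency(trait_genes, min_count):
    counts = brute_gene_counts(trait_genes)
    return {g for g, n in counts.items() if n >= min_count}


def brute_intersection(sets):
    sets = [set(s) for s in sets]
    out = set(sets[0])
    for s in sets[1:]:
        out = {g for g in out if g in s}
    return out
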