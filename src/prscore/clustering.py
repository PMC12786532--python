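"""Disease similarity: Jaccard distances, t-SNE embedding, clustering.

Diseases are points, genes are binary features.  All geometry runs off the
precomputed Jaccard distance matrix (1 − Jaccard similarity of the gene
sets).  The t-SNE embedding is for visualization; cluster membership is
assigned reproducibly by average-linkage agglomerative clustering on the
same distances, and partitions from different size strata are compared with
the adjusted Rand index.

With only a handful of diseases the textbook rule of thumb n > 3·perplexity
fails; small panels are accepted by capping the perplexity at (n−1)/3 with a
warning rather than refusing to embed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.manifold import TSNE
from sklearn.metrics import adjusted_rand_score

from .core_matrix import GenePresenceMatrix
from .overlap_stats import pairwise_overlap

__all__ = [
    "EmbeddingResult",
    "ClusterAssignment",
    "jaccard_distance_matrix",
    "tsne_embed",
    "hierarchical_clusters",
    "cluster_stability",
    "plot_similarity_heatmap",
    "plot_embedding",
]


@dataclass
class EmbeddingResult:
    """2-D t-SNE coordinates for each disease."""

    coords: dict[str, tuple[float, float]]
    perplexity: float
    seed: int
    metric: str = "jaccard"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(t, x, y) for t, (x, y) in sorted(self.coords.items())],
            columns=["trait", "x", "y"],
        )


@dataclass
class ClusterAssignment:
    """Disease → cluster id labeling; ids are contiguous from 1."""

    labels: dict[str, int]
    method: str
    k: int

    def members(self, cluster_id: int) -> set[str]:
        return {t for t, c in self.labels.items() if c == cluster_id}


def jaccard_distance_matrix(matrix: GenePresenceMatrix) -> pd.DataFrame:
    """Symmetric disease×disease matrix of 1 − Jaccard, zero diagonal."""
    diseases = matrix.diseases
    dist = pd.DataFrame(0.0, index=diseases, columns=diseases)
    for res in pairwise_overlap(matrix):
        a, b = res.pair
        dist.loc[a, b] = dist.loc[b, a] = 1.0 - res.jaccard
    return dist


def _capped_perplexity(perplexity: float, n: int) -> float:
    cap = (n - 1) / 3
    if perplexity > cap:
        warnings.warn(
            f"perplexity {perplexity} too large for {n} samples; capped at {cap:.2f}",
            UserWarning,
            stacklevel=3,
        )
        return cap
    return perplexity


def tsne_embed(
    matrix: GenePresenceMatrix, perplexity: float = 3.0, seed: int = 42
) -> EmbeddingResult:
    """Embed diseases in 2-D by t-SNE on the precomputed Jaccard distances.

    Deterministic for a fixed seed.  Fewer than 3 diseases cannot be
    embedded; a perplexity too large for the panel is capped (warning).
    """
    diseases = matrix.diseases
    n = len(diseases)
    if n < 3:
        raise ValueError("t-SNE embedding needs at least 3 traits")
    perplexity = _capped_perplexity(perplexity, n)
    dist = jaccard_distance_matrix(matrix)
    tsne = TSNE(
        n_components=2,
        metric="precomputed",
        init="random",
        perplexity=perplexity,
        random_state=seed,
    )
    coords = tsne.fit_transform(dist.to_numpy())
    return EmbeddingResult(
        coords={t: (float(x), float(y)) for t, (x, y) in zip(diseases, coords)},
        perplexity=perplexity,
        seed=seed,
    )


def hierarchical_clusters(distances: pd.DataFrame, k: int) -> ClusterAssignment:
    """Average-linkage agglomerative clustering cut at ``k`` clusters.

    Traits are ordered lexicographically before linkage so ties in the merge
    sequence resolve identically across runs.  Cluster ids are renumbered
    contiguously from 1 in order of first appearance.
    """
    traits = sorted(distances.index)
    n = len(traits)
    if not (2 <= k <= n - 1):
        raise ValueError(f"k must lie in [2, {n - 1}], got {k}")
    dist = distances.loc[traits, traits].to_numpy()
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    raw = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels: dict[str, int] = {}
    for trait, cid in zip(traits, raw):
        if cid not in relabel:
            relabel[cid] = len(relabel) + 1
        labels[trait] = relabel[cid]
    return ClusterAssignment(labels=labels, method="average-linkage/jaccard", k=k)


def cluster_stability(assignments: list[ClusterAssignment]) -> pd.DataFrame:
    """Pairwise adjusted Rand index between partitions of the same traits.

    1.0 means two partitions are identical up to relabeling; values near 0
    indicate chance-level agreement.
    """
    if len(assignments) < 2:
        raise ValueError("need at least 2 assignments to compare")
    trait_sets = [frozenset(a.labels) for a in assignments]
    if len(set(trait_sets)) != 1:
        raise ValueError("assignments cover different trait sets")
    traits = sorted(trait_sets[0])
    n = len(assignments)
    ari = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a = [assignments[i].labels[t] for t in traits]
            b = [assignments[j].labels[t] for t in traits]
            ari[i, j] = ari[j, i] = adjusted_rand_score(a, b)
    names = [f"partition_{i}" for i in range(n)]
    return pd.DataFrame(ari, index=names, columns=names)


def _leaf_order(distances: pd.DataFrame) -> list[str]:
    traits = sorted(distances.index)
    dist = distances.loc[traits, traits].to_numpy()
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return [traits[i] for i in hierarchy.leaves_list(linkage)]


def plot_similarity_heatmap(
    matrix: GenePresenceMatrix, path: str | Path
) -> None:
    """Jaccard-similarity heatmap with traits in clustering leaf order."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    dist = jaccard_distance_matrix(matrix)
    order = _leaf_order(dist)
    sim = 1.0 - dist.loc[order, order]
    fig, ax = plt.subplots(figsize=(7, 6))
    sns.heatmap(sim, ax=ax, cmap="viridis", vmin=0, vmax=1, square=True)
    ax.set_title(f"Gene-set Jaccard similarity ({matrix.stratum_label})")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_embedding(
    embedding: EmbeddingResult,
    path: str | Path,
    clusters: ClusterAssignment | None = None,
) -> None:
    """Scatter the t-SNE coordinates, colored by cluster when given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    frame = embedding.to_frame()
    if clusters is not None:
        frame["cluster"] = [clusters.labels[t] for t in frame["trait"]]
    fig, ax = plt.subplots(figsize=(7, 6))
    sns.scatterplot(
        data=frame,
        x="x",
        y="y",
        hue="cluster" if clusters is not None else None,
        palette="deep" if clusters is not None else None,
        s=80,
        ax=ax,
    )
    for _, row in frame.iterrows():
        ax.annotate(row["trait"], (row["x"], row["y"]), fontsize=8,
                    xytext=(3, 3), textcoords="offset points")
    ax.set_title(f"t-SNE of disease gene sets (perplexity={embedding.perplexity:g})")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
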