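"""Minimal built-in clusterers.

These exist so an end-to-end consensus run needs no external clustering
software: a k-means-on-PCA baseline and a KNN-graph community-detection
baseline.  They are deliberately simple plumbing — real pipelines plug in
assignment tables from whatever algorithms the user trusts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .assignments import ClusterAssignment
from .errors import ValidationError

__all__ = ["baseline_kmeans_embed", "baseline_graph_community"]


def _embed(counts: pd.DataFrame, n_components: int = 50) -> np.ndarray:
    """Log-normalise counts and reduce to at most 50 principal directions."""
    X = counts.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValidationError("counts must be non-negative")
    lib = X.sum(axis=1)
    lib[lib == 0] = 1.0
    X = np.log1p(X / lib[:, None] * np.median(lib))
    n_comp = min(n_components, X.shape[0] - 1, X.shape[1])
    return PCA(n_components=n_comp, random_state=0).fit_transform(X)


def baseline_kmeans_embed(
    counts: pd.DataFrame, k: int, seed: int = 0, algorithm_name: str = "kmeans_embed"
) -> ClusterAssignment:
    """k-means on a log-normalised PCA embedding of the counts."""
    if k < 2:
        raise ValidationError("k must be >= 2")
    if k > counts.shape[0]:
        raise ValidationError(f"k={k} exceeds number of cells ({counts.shape[0]})")
    emb = _embed(counts)
    labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(emb)
    return ClusterAssignment(
        algorithm_name=algorithm_name,
        cell_ids=tuple(str(c) for c in counts.index),
        labels=tuple(str(l + 1) for l in labels),
    )


def baseline_graph_community(
    counts: pd.DataFrame,
    resolution: float = 1.0,
    seed: int = 0,
    n_neighbors: int = 15,
    algorithm_name: str = "graph_community",
) -> ClusterAssignment:
    """Leiden community detection on a KNN graph of the embedding.

    The number of clusters is not fixed; ``resolution`` trades cluster
    granularity (higher → more clusters).
    """
    import igraph as ig
    import leidenalg

    emb = _embed(counts)
    m = emb.shape[0]
    nn = min(n_neighbors, m - 1)
    knn = NearestNeighbors(n_neighbors=nn + 1).fit(emb)
    _, idx = knn.kneighbors(emb)
    edges = {(min(i, j), max(i, j)) for i in range(m) for j in idx[i, 1:]}
    g = ig.Graph(n=m, edges=sorted(edges))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
    )
    return ClusterAssignment(
        algorithm_name=algorithm_name,
        cell_ids=tuple(str(c) for c in counts.index),
        labels=tuple(str(l + 1) for l in part.membership),
    )
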