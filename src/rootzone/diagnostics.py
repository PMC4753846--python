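"""Sample-relationship diagnostics: leading-fold-change distances, average-
linkage clustering and classical multidimensional scaling.

The distance between two samples is the root-mean-square of the top-k
largest absolute log2 expression differences between them (the leading log2
fold change), emphasizing the genes that separate the pair most strongly.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, to_tree
from scipy.spatial.distance import squareform


def sample_distances(logged: pd.DataFrame, top_k: int = 500) -> pd.DataFrame:
    """Pairwise leading-log2-fold-change distance matrix (samples x samples)."""
    x = logged.to_numpy(float)
    n_genes, n_samples = x.shape
    if top_k > n_genes:
        warnings.warn(
            f"top_k={top_k} exceeds the {n_genes} available genes; clamping"
        )
        top_k = n_genes
    d = np.zeros((n_samples, n_samples))
    for i in range(n_samples):
        for j in range(i + 1, n_samples):
            diff2 = (x[:, i] - x[:, j]) ** 2
            top = np.sort(diff2)[-top_k:]
            d[i, j] = d[j, i] = np.sqrt(top.mean())
    return pd.DataFrame(d, index=logged.columns, columns=logged.columns)


def cluster_tree(distances: pd.DataFrame) -> str:
    """Average-linkage hierarchical clustering of a distance matrix, as Newick."""
    condensed = squareform(distances.to_numpy(), checks=False)
    linkage = average(condensed)
    root = to_tree(linkage)
    labels = list(distances.index)

    def newick(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = newick(node.left, node.dist)
        right = newick(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({newick(root.left, root.dist)},{newick(root.right, root.dist)});"


def mds_embedding(distances: pd.DataFrame, n_dims: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) scaling of the distance matrix."""
    d2 = distances.to_numpy() ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:n_dims]
    coords = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
    return pd.DataFrame(
        coords,
        index=distances.index,
        columns=[f"dim{i + 1}" for i in range(n_dims)],
    )
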