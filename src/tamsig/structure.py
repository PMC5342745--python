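"""Sample-similarity reporting and co-regulated-module extraction.

Correlation heatmaps and PCA operate on log2(TPM+1).  Gene modules are
found by agglomerative clustering with correlation distance (d = 1 - r)
and WPGMA ("weighted") linkage, and read off the dendrogram by cutting at
a fixed height.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from skbio import TreeNode

log = logging.getLogger(__name__)


def pearson_matrix(x: pd.DataFrame, axis: str = "samples") -> pd.DataFrame:
    """Symmetric Pearson correlation matrix between samples or genes.

    Zero-variance entities are excluded (with a log message) rather than
    yielding NaN rows.
    """
    if axis not in ("samples", "genes"):
        raise ValueError("axis must be 'samples' or 'genes'")
    data = x if axis == "genes" else x.T     # rows = entities
    if data.shape[0] < 2:
        raise ValueError("need >= 2 entities to correlate")
    if data.shape[1] < 3:
        raise ValueError("need >= 3 observations per correlation vector")
    sd = data.std(axis=1, ddof=0)
    flat = sd.index[sd == 0]
    if len(flat):
        log.info("pearson_matrix: excluding %d zero-variance entities", len(flat))
        data = data.drop(index=flat)
    r = np.corrcoef(data.to_numpy(dtype=float))
    return pd.DataFrame(r, index=data.index, columns=data.index)


def pca(x: pd.DataFrame, n_components: int | None = None):
    """Gene-centered SVD of a log-scale matrix.

    Returns (coordinates, explained_variance_fractions): coordinates is a
    samples x components DataFrame.  The sign of each component is fixed so
    that its largest-magnitude gene loading is positive.
    """
    if x.shape[1] < 2:
        raise ValueError("PCA needs >= 2 samples")
    X = x.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(len(s), x.shape[1] - 1) if x.shape[1] > 1 else 1
    k = k if n_components is None else min(n_components, k)
    for i in range(k):
        j = np.argmax(np.abs(U[:, i]))
        if U[j, i] < 0:
            U[:, i] *= -1
            Vt[i] *= -1
    coords = pd.DataFrame((Vt[:k].T * s[:k]), index=x.columns,
                          columns=[f"PC{i + 1}" for i in range(k)])
    total = (s ** 2).sum()
    evr = s[:k] ** 2 / total if total > 0 else np.zeros(k)
    return coords, evr


@dataclass
class DistanceTree:
    """WPGMA merge history over a gene set with correlation distance."""

    linkage: np.ndarray
    leaves: list
    method: str = "weighted"
    metric: str = "correlation"

    def to_newick(self) -> str:
        tree = TreeNode.from_linkage_matrix(self.linkage, self.leaves)
        return str(tree)


def hcluster(x_genes: pd.DataFrame) -> DistanceTree:
    """Cluster gene profiles with d = 1 - Pearson r and WPGMA linkage.

    Zero-variance genes cannot enter a correlation distance and are
    excluded with a log message.
    """
    sd = x_genes.std(axis=1, ddof=0)
    flat = sd.index[sd == 0]
    if len(flat):
        log.info("hcluster: excluding %d zero-variance genes", len(flat))
        x_genes = x_genes.drop(index=flat)
    if x_genes.shape[0] < 2:
        raise ValueError("need >= 2 genes with nonzero variance to cluster")
    Z = hierarchy.linkage(x_genes.to_numpy(dtype=float),
                          method="weighted", metric="correlation")
    return DistanceTree(Z, list(x_genes.index))


def extract_modules(tree: DistanceTree, cut_height: float = 0.5):
    """Flat clusters at the cut height, largest first."""
    labels = hierarchy.fcluster(tree.linkage, t=cut_height, criterion="distance")
    modules = {}
    for gene, lab in zip(tree.leaves, labels):
        modules.setdefault(lab, []).append(gene)
    return sorted((sorted(m) for m in modules.values()),
                  key=lambda m: (-len(m), m[0]))
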