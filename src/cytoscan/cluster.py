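"""Unsupervised clustering of samples on cytoband scores.

Tumor subtypes leave distinct cytogenetic footprints, so agglomerative
hierarchical clustering of the sample-by-cytoband score matrix should
recover them.  Flat labels for a requested ``k`` are cut from the tree
and canonically renumbered by first appearance (lowest sample index), so
results are deterministic.  Subtype-recovery accuracy is measured by the
best one-to-one mapping of cluster labels onto truth classes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, ClusterMixin

DISTANCES = ("euclidean", "correlation")
LINKAGES = ("average", "ward", "complete")


@dataclass
class ClusterResult:
    linkage: np.ndarray  # scipy linkage matrix (merge topology + heights)
    labels: np.ndarray  # flat labels 0..k-1, renumbered by first appearance
    sample_ids: list
    k: int

    def assignments(self) -> pd.Series:
        return pd.Series(self.labels, index=self.sample_ids, name="cluster")


def cluster_samples(
    scores: pd.DataFrame | np.ndarray,
    k: int,
    distance: str = "euclidean",
    linkage: str = "ward",
) -> ClusterResult:
    """Hierarchical clustering of score-matrix rows into ``k`` flat clusters."""
    if distance not in DISTANCES:
        raise ValueError(f"distance must be one of {DISTANCES}")
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    if linkage == "ward" and distance != "euclidean":
        raise ValueError("ward linkage requires euclidean distance")
    if isinstance(scores, pd.DataFrame):
        ids = list(scores.index)
        X = scores.to_numpy(dtype=float)
    else:
        X = np.asarray(scores, dtype=float)
        ids = list(range(len(X)))
    n = len(X)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}")
    Z = hierarchy.linkage(pdist(X, metric=distance), method=linkage)
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    # renumber clusters by order of first appearance
    remap, labels = {}, np.empty(n, dtype=int)
    for i, lab in enumerate(raw):
        labels[i] = remap.setdefault(lab, len(remap))
    return ClusterResult(linkage=Z, labels=labels, sample_ids=ids, k=int(labels.max()) + 1)


def to_newick(result: ClusterResult) -> str:
    """Dendrogram in Newick format, branch lengths = merge-height deltas."""
    Z = result.linkage
    n = len(result.sample_ids)
    heights = {i: 0.0 for i in range(n)}

    def name(i):
        return str(result.sample_ids[i]).replace(" ", "_")

    subtrees = {i: name(i) for i in range(n)}
    for j, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        node = n + j
        subtrees[node] = (
            f"({subtrees[a]}:{h - heights[a]:.10g},{subtrees[b]}:{h - heights[b]:.10g})"
        )
        heights[node] = h
    return subtrees[n + len(Z) - 1] + ";" if len(Z) else subtrees[0] + ";"


def mapped_accuracy(labels, truth) -> float:
    """Subtype-recovery accuracy under the best one-to-one label mapping.

    Cluster labels are matched to truth classes by maximum-agreement
    assignment (Hungarian algorithm); unmatched clusters count all their
    members as errors.  Invariant under relabeling of either side.
    """
    labels = np.asarray(labels)
    truth = np.asarray(truth)
    if labels.shape != truth.shape:
        raise ValueError("labels and truth must have equal length")
    if len(labels) == 0:
        raise ValueError("empty label vectors")
    table = pd.crosstab(pd.Series(labels), pd.Series(truth)).to_numpy()
    rows, cols = linear_sum_assignment(table, maximize=True)
    return float(table[rows, cols].sum()) / len(labels)


class SubtypeClusterer(ClusterMixin, BaseEstimator):
    """Sklearn-style wrapper: ``fit`` stores ``labels_`` and ``linkage_``."""

    def __init__(self, n_clusters: int = 4, distance: str = "euclidean",
                 linkage: str = "ward"):
        self.n_clusters = n_clusters
        self.distance = distance
        self.linkage = linkage

    def fit(self, X, y=None):
        result = cluster_samples(X, self.n_clusters, self.distance, self.linkage)
        self.labels_ = result.labels
        self.linkage_ = result.linkage
        self.result_ = result
        return self
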