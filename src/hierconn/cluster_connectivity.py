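"""Inter-cluster connectivity and its decay along the hierarchy tree.

For a partition of the nodes, the connectivity from cluster X to cluster Y
sums every weight emanating from a node of X and terminating in a node of Y,
normalized by the total weight emanating from X — so each row of the
resulting matrix ``b`` sums to 1 and ``b[X][X]`` is X's self-connectivity
(within-cluster edges are counted from both endpoints). Grouping the ``b``
values by the tree distance between clusters and averaging yields a
distance profile; on hierarchically organized networks the profile decays
geometrically, and the per-level fold-change is estimated both as
``exp(-slope)`` of a log-linear fit and as the vector of adjacent-distance
ratios.

Self-connectivity (distance 0) aggregates all residual structure inside a
cluster — at coarse tiers that includes every deeper level of the hierarchy —
so the decay estimate uses the strictly between-cluster distances (t >= 1)
whenever at least two of them are available, and falls back to the full
profile otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from hierconn.io import _validate_matrix
from hierconn.tree import ClusterNode, ClusterTree

logger = logging.getLogger(__name__)


@dataclass
class InterClusterMatrix:
    """Normalized cluster-to-cluster connectivity at one tier.

    ``b[X][Y]`` is the fraction of X's outgoing weight that lands in Y; rows
    sum to 1 unless a cluster has no outgoing weight (flagged in
    ``zero_rows``).
    """

    clusters: list[ClusterNode]
    b: np.ndarray
    zero_rows: np.ndarray


@dataclass
class TreeDistanceProfile:
    """Mean normalized inter-cluster connectivity per tree distance.

    ``decay_ratio`` is the fitted per-level fold-change (exp(-slope) of the
    log-linear fit over the distances used); ``adjacent_ratios`` lists
    mean(t)/mean(t+1) for consecutive distances; ``fit_quality`` is the R^2
    of the log-linear fit. ``fit_distances`` records which distances entered
    the fit; ``decay_ratio`` is NaN when fewer than two usable distances
    exist.
    """

    distances: np.ndarray
    mean_connectivity: np.ndarray
    n_pairs: np.ndarray
    decay_ratio: float
    adjacent_ratios: np.ndarray
    fit_quality: float
    fit_distances: np.ndarray


def between_cluster_connectivity(
    matrix: np.ndarray, clusters: Sequence[ClusterNode] | Sequence[Sequence[int]]
) -> InterClusterMatrix:
    """Normalized connectivity between the clusters of one partition.

    The numerator for (X, Y) sums w_ij over ordered pairs with i in X,
    j in Y, i != j; the denominator is X's total outgoing weight, so rows
    are stochastic. Clusters must partition the node set.
    """
    w = _validate_matrix(matrix)
    n = w.shape[0]
    nodes: list[ClusterNode] = [
        c if isinstance(c, ClusterNode) else ClusterNode(tuple(c), 0) for c in clusters
    ]
    member_lists = [list(c.members) for c in nodes]
    flat = sorted(i for members in member_lists for i in members)
    if flat != list(range(n)):
        raise ValueError("clusters must partition the node set exactly")
    k = len(nodes)
    sums = np.zeros((k, k))
    for a, mem_a in enumerate(member_lists):
        for b_idx, mem_b in enumerate(member_lists):
            sums[a, b_idx] = w[np.ix_(mem_a, mem_b)].sum()
    out_weight = sums.sum(axis=1)
    zero_rows = out_weight == 0
    if zero_rows.any():
        logger.warning("%d cluster(s) have no outgoing weight", int(zero_rows.sum()))
    b = np.zeros((k, k))
    b[~zero_rows] = sums[~zero_rows] / out_weight[~zero_rows, None]
    return InterClusterMatrix(clusters=nodes, b=b, zero_rows=zero_rows)


def tree_distance(tree: ClusterTree, x: ClusterNode, y: ClusterNode) -> int:
    """Tiers separating two same-tier clusters from their first common
    ancestor: 0 for the same cluster, 1 for siblings."""
    return tree.distance(x, y)


def distance_profile(
    matrix: np.ndarray, tree: ClusterTree, tier: int
) -> TreeDistanceProfile:
    """Average the inter-cluster connectivity at one tier by tree distance
    and fit the per-level decay.

    Ordered cluster pairs (including X = Y) are grouped by tree distance; the
    mean of ``b`` within each group gives the profile. Distances with zero
    mean are dropped from the log-linear fit with a warning rather than
    pseudocounted.
    """
    partition = tree.partition_at(tier)
    icm = between_cluster_connectivity(matrix, partition)
    k = len(partition)
    dist = np.zeros((k, k), dtype=int)
    for a in range(k):
        for b_idx in range(k):
            dist[a, b_idx] = tree.distance(partition[a], partition[b_idx], tier=tier)

    distances = np.unique(dist)
    means = np.array([icm.b[dist == t].mean() for t in distances])
    n_pairs = np.array([(dist == t).sum() for t in distances])

    with np.errstate(divide="ignore", invalid="ignore"):
        adjacent = np.where(
            means[1:] > 0, means[:-1] / np.where(means[1:] > 0, means[1:], 1.0), np.nan
        )

    positive = means > 0
    if not positive.all():
        logger.warning(
            "tree distance(s) %s have zero mean connectivity; dropped from fit",
            distances[~positive].tolist(),
        )
    between = positive & (distances >= 1)
    use = between if between.sum() >= 2 else positive
    if use.sum() >= 2:
        t_fit = distances[use].astype(float)
        log_m = np.log(means[use])
        slope, intercept = np.polyfit(t_fit, log_m, 1)
        predicted = slope * t_fit + intercept
        ss_res = float(((log_m - predicted) ** 2).sum())
        ss_tot = float(((log_m - log_m.mean()) ** 2).sum())
        ratio = float(np.exp(-slope))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        fit_distances = distances[use]
    else:
        logger.warning("fewer than two usable distances; decay fit skipped")
        ratio, r2 = float("nan"), float("nan")
        fit_distances = distances[use]
    return TreeDistanceProfile(
        distances=distances,
        mean_connectivity=means,
        n_pairs=n_pairs,
        decay_ratio=ratio,
        adjacent_ratios=adjacent,
        fit_quality=float(r2),
        fit_distances=fit_distances,
    )
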