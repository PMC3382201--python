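"""Weighted clustering, shortest paths, betweenness, and the small-world index.

Two weighted clustering coefficients are provided: the Onnela geometric-mean
form, which normalizes each triangle's weight product by the node's binary
degree, and the Grindrod-Zhang-Horvath (GZH) form, which depends on
connection weights only. Both normalize weights by the largest edge weight in
the network, so they are invariant under global rescaling and lie in [0, 1].

Connectivity weights represent potential information flow, so they are
transformed to distances as d = 1/w before shortest-path computations
(stronger connections are shorter). The small-world index compares mean
clustering and mean shortest path length against weight-shuffled null
networks that preserve the full multiset of edge weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from hierconn.io import _validate_matrix


@dataclass
class SmallWorldReport:
    """Small-world summary of one weighted network against shuffled nulls.

    gamma = C / C_rand, lambda_ = L / L_rand, sw_index = gamma / lambda_.
    ``n_infinite_pairs`` counts node pairs with no connecting path in the
    input network (excluded from L and reported separately).
    """

    cc_mean: float
    path_mean: float
    cc_rand_mean: float
    path_rand_mean: float
    gamma: float
    lambda_: float
    sw_index: float
    n_rand: int
    cc_formula: str
    n_infinite_pairs: int


def _normalized(w: np.ndarray) -> np.ndarray:
    w = _validate_matrix(w)
    wmax = w.max()
    if wmax == 0:
        raise ValueError("all-zero matrix has no clustering structure")
    return w / wmax


def onnela_clustering(matrix: np.ndarray) -> np.ndarray:
    """Per-node Onnela weighted clustering coefficient.

    With w_hat = w / max(w) and k_i the number of nonzero neighbors:
    C_i = [2 / (k_i (k_i - 1))] * sum over neighbor pairs of
    (w_hat_ij * w_hat_ih * w_hat_jh)^(1/3). Nodes with fewer than two
    neighbors get 0.
    """
    w_hat = _normalized(matrix)
    cbrt = np.cbrt(w_hat)
    k = np.count_nonzero(w_hat, axis=1)
    triangles = np.diagonal(cbrt @ cbrt @ cbrt)  # 2 * sum over j<h of products
    denom = k * (k - 1)
    out = np.zeros(w_hat.shape[0])
    ok = denom > 0
    out[ok] = triangles[ok] / denom[ok]
    return out


def gzh_clustering(matrix: np.ndarray) -> np.ndarray:
    """Per-node Grindrod-Zhang-Horvath weighted clustering coefficient.

    C_i = sum_{j != h} w_hat_ij w_hat_jh w_hat_hi
          / [ (sum_j w_hat_ij)^2 - sum_j w_hat_ij^2 ],
    with 0 where the denominator vanishes. Depends on weights only; on a
    0/max-weight graph it reduces to the binary clustering coefficient.
    """
    w_hat = _normalized(matrix)
    numerator = np.diagonal(w_hat @ w_hat @ w_hat)
    row = w_hat.sum(axis=1)
    denom = row**2 - (w_hat**2).sum(axis=1)
    out = np.zeros(w_hat.shape[0])
    ok = denom > 0
    out[ok] = numerator[ok] / denom[ok]
    return out


def weight_to_distance(matrix: np.ndarray) -> np.ndarray:
    """Transform weights to distances: d = 1/w for w > 0, inf for absent
    edges, 0 on the diagonal."""
    w = _validate_matrix(matrix)
    with np.errstate(divide="ignore"):
        d = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    np.fill_diagonal(d, 0.0)
    return d


def shortest_paths(distance_matrix: np.ndarray) -> np.ndarray:
    """Exact all-pairs geodesic lengths (Johnson's algorithm).

    ``distance_matrix`` uses inf (or 0 off-diagonal) for absent edges;
    unreachable pairs come back as inf.
    """
    d = np.asarray(distance_matrix, dtype=float)
    n = d.shape[0]
    i, j = np.nonzero(np.isfinite(d) & (d > 0))
    graph = csr_matrix((d[i, j], (i, j)), shape=(n, n))
    return _csgraph_shortest_path(graph, method="J", directed=False)


def average_path_length(geodesics: np.ndarray) -> tuple[float, int]:
    """Mean geodesic over unordered distinct finite pairs, plus the number of
    infinite (disconnected) pairs."""
    g = np.asarray(geodesics, dtype=float)
    iu, ju = np.triu_indices(g.shape[0], k=1)
    vals = g[iu, ju]
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("no finite pairs: network is fully disconnected")
    return float(vals[finite].mean()), int((~finite).sum())


def betweenness(matrix: np.ndarray) -> np.ndarray:
    """Per-node betweenness centrality on d = 1/w distances.

    Fraction of shortest paths between other node pairs passing through each
    node, with fractional credit for ties, normalized by (N-1)(N-2)/2.
    """
    d = weight_to_distance(matrix)
    n = d.shape[0]
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    i, j = np.nonzero(np.triu(np.isfinite(d), k=1))
    graph.add_weighted_edges_from(zip(i.tolist(), j.tolist(), d[i, j].tolist()))
    bc = nx.betweenness_centrality(graph, weight="weight", normalized=True)
    return np.array([bc[v] for v in range(n)])


def shuffle_null(matrix: np.ndarray, seed: int | np.random.Generator) -> np.ndarray:
    """Null network preserving the weight multiset: uniformly permute all
    N(N-1)/2 upper-triangle values (zeros included) over positions, then
    mirror for symmetry."""
    w = _validate_matrix(matrix)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = w.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = rng.permutation(w[iu, ju])
    out = np.zeros_like(w)
    out[iu, ju] = vals
    out[ju, iu] = vals
    return out


def _cc_mean(matrix: np.ndarray, cc_formula: str) -> float:
    if cc_formula == "onnela":
        return float(onnela_clustering(matrix).mean())
    if cc_formula == "gzh":
        return float(gzh_clustering(matrix).mean())
    raise ValueError(f"cc_formula must be 'onnela' or 'gzh', not {cc_formula!r}")


def small_world_index(
    matrix: np.ndarray,
    n_rand: int = 1000,
    seed: int = 0,
    cc_formula: str = "onnela",
) -> SmallWorldReport:
    """Small-world index sigma = (C/C_rand) / (L/L_rand) against shuffled nulls.

    C and L are computed on the input; C_rand and L_rand are means over
    ``n_rand`` weight-shuffled null networks. A value well above 1 indicates
    clustering far exceeding the null at comparable path length.
    """
    if n_rand < 1:
        raise ValueError("n_rand must be at least 1")
    w = _validate_matrix(matrix)
    cc = _cc_mean(w, cc_formula)
    path, n_inf = average_path_length(shortest_paths(weight_to_distance(w)))

    rng = np.random.default_rng(seed)
    cc_rand = np.empty(n_rand)
    path_rand = np.empty(n_rand)
    got_any = False
    for r in range(n_rand):
        null = shuffle_null(w, rng)
        cc_rand[r] = _cc_mean(null, cc_formula)
        try:
            path_rand[r], _ = average_path_length(shortest_paths(weight_to_distance(null)))
            got_any = True
        except ValueError:
            path_rand[r] = np.nan
    if not got_any:
        raise ValueError("every null network was fully disconnected")

    cc_rand_mean = float(cc_rand.mean())
    path_rand_mean = float(np.nanmean(path_rand))
    if cc_rand_mean == 0.0:
        raise ValueError(
            "null networks contain no closed triangles; the normalized "
            "clustering coefficient is undefined for this input"
        )
    gamma = cc / cc_rand_mean
    lambda_ = path / path_rand_mean
    return SmallWorldReport(
        cc_mean=cc,
        path_mean=path,
        cc_rand_mean=cc_rand_mean,
        path_rand_mean=path_rand_mean,
        gamma=gamma,
        lambda_=lambda_,
        sw_index=gamma / lambda_,
        n_rand=n_rand,
        cc_formula=cc_formula,
        n_infinite_pairs=n_inf,
    )
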