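"""k-nearest-neighbor hypergraphs over omics features.

A hypergraph G(V, E, w) generalizes a graph by letting each hyperedge join
any number of vertices.  Here the vertices are the features (genes, CpG
sites, ...) of one omics block and one hyperedge is planted per feature,
containing that feature and its ``k - 1`` nearest neighbors in profile
space.  From the binary incidence matrix H (N vertices x M hyperedges) the
usual spectral objects are derived:

* edge weights ``w`` (diagonal of W),
* vertex degrees ``Dv[i] = sum_e w(e) H[i, e]``,
* edge degrees ``De[e] = sum_i H[i, e]``,
* similarity ``S = H W De^-1 H^T``,
* normalized Laplacian ``L = I - Dv^-1/2 S Dv^-1/2``.

The quadratic form ``g^T L g`` penalizes weight differences between
hyperedge-linked features and is the regularizer consumed by the solver.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "Hypergraph",
    "build_knn_hypergraph",
    "similarity_and_laplacian",
    "build_knn_graph",
    "write_incidence_tsv",
]


class HypergraphError(ValueError):
    """Invalid hypergraph construction parameters or degenerate structure."""


@dataclass
class Hypergraph:
    """A weighted hypergraph with its derived spectral matrices.

    ``similarity`` and ``laplacian`` are populated by
    :func:`similarity_and_laplacian`; ``normalized_similarity`` is the
    degree-normalized affinity ``Dv^-1/2 S Dv^-1/2`` used directly by the
    solver's coordinate updates (``L = I - normalized_similarity``).
    """

    incidence: np.ndarray
    edge_weights: np.ndarray
    vertex_degrees: np.ndarray = field(default=None)  # type: ignore[assignment]
    edge_degrees: np.ndarray = field(default=None)  # type: ignore[assignment]
    similarity: np.ndarray = field(default=None)  # type: ignore[assignment]
    laplacian: np.ndarray = field(default=None)  # type: ignore[assignment]
    normalized_similarity: np.ndarray = field(default=None)  # type: ignore[assignment]
    # max(0, lambda_max(L) - 1): curvature excess over the hypergraph bound,
    # consumed by the solver's majorize-minimize sweep.  Zero for KNN
    # hypergraphs (their normalized similarity is PSD, so eig(L) <= 1).
    mm_shift: float = 0.0

    @property
    def n_vertices(self) -> int:
        return self.incidence.shape[0]

    @property
    def n_edges(self) -> int:
        return self.incidence.shape[1]


def _zscore_profiles(profiles: np.ndarray) -> np.ndarray:
    """Row-wise z-score; constant rows are left unscaled with a warning."""
    mean = profiles.mean(axis=1, keepdims=True)
    sd = profiles.std(axis=1, keepdims=True)
    constant = (sd[:, 0] == 0.0)
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature profile(s); "
            "z-scoring skipped for them in neighbor search",
            stacklevel=3,
        )
    sd = np.where(sd == 0.0, 1.0, sd)
    out = (profiles - mean) / sd
    out[constant] = profiles[constant]  # z-scoring dropped for constant rows
    return out


def build_knn_hypergraph(
    profiles: np.ndarray,
    k: int = 2,
    metric: str = "euclidean",
    weighting: str = "uniform",
    heat_sigma: float | None = None,
) -> Hypergraph:
    """Build the KNN hypergraph of a feature-profile matrix.

    Parameters
    ----------
    profiles
        ``N features x n samples`` matrix; one row per vertex.  Rows are
        z-scored before distances are computed.
    k
        Number of vertices per hyperedge: the centroid feature plus its
        ``k - 1`` nearest neighbors.  ``k = 1`` yields singleton hyperedges
        and a zero Laplacian (no coupling), which is warned about.
    metric
        ``"euclidean"`` or ``"correlation"`` (1 - Pearson r).
    weighting
        ``"uniform"`` (w = 1, default) or ``"heat"``:
        ``w(e) = exp(-mean pairwise dist^2 / sigma^2)`` with ``sigma`` equal
        to ``heat_sigma`` or the global median pairwise distance.

    Notes
    -----
    Neighbor ties are broken by ascending feature index (stable sort), so
    the construction is fully deterministic.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2:
        raise HypergraphError("profiles must be a 2-D (features x samples) array")
    n_feat, n_obs = profiles.shape
    if n_feat < 2 or n_obs < 2:
        raise HypergraphError("need at least 2 features and 2 samples")
    if not (1 <= k <= n_feat):
        raise HypergraphError(f"k={k} must satisfy 1 <= k <= n_features={n_feat}")
    if not np.isfinite(profiles).all():
        raise HypergraphError("profiles contain non-finite values")
    if metric not in ("euclidean", "correlation"):
        raise HypergraphError(f"unknown metric {metric!r}")
    if k == 1:
        warnings.warn(
            "k=1 builds singleton hyperedges: the Laplacian is zero and the "
            "hypergraph penalty is inert",
            stacklevel=2,
        )

    z = _zscore_profiles(profiles)
    dist = cdist(z, z, metric="euclidean" if metric == "euclidean" else "correlation")
    np.fill_diagonal(dist, 0.0)

    incidence = np.zeros((n_feat, n_feat), dtype=float)
    # one hyperedge per feature: {j} plus k-1 nearest neighbors of j; stable
    # argsort breaks distance ties by ascending feature index
    for j in range(n_feat):
        d = dist[j].copy()
        d[j] = -np.inf  # the centroid always belongs to its own hyperedge
        order = np.argsort(d, kind="stable")
        incidence[order[:k], j] = 1.0

    if weighting == "uniform":
        weights = np.ones(n_feat)
    elif weighting == "heat":
        weights = np.empty(n_feat)
        off = dist[~np.eye(n_feat, dtype=bool)]
        sigma = heat_sigma if heat_sigma is not None else max(np.median(off), 1e-12)
        for j in range(n_feat):
            members = np.flatnonzero(incidence[:, j])
            if members.size < 2:
                weights[j] = 1.0
                continue
            sub = dist[np.ix_(members, members)]
            mean_sq = (sub[~np.eye(members.size, dtype=bool)] ** 2).mean()
            weights[j] = np.exp(-mean_sq / sigma**2)
    else:
        raise HypergraphError(f"unknown weighting {weighting!r}")

    hg = Hypergraph(incidence=incidence, edge_weights=weights)
    return similarity_and_laplacian(hg)


def similarity_and_laplacian(hg: Hypergraph) -> Hypergraph:
    """Populate degrees, similarity S and normalized Laplacian L in place.

    ``S = H W De^-1 H^T`` and ``L = I - Dv^-1/2 S Dv^-1/2``.  Raises if any
    vertex is isolated (degree zero), since the normalization is then
    undefined; increase ``k`` or prune the feature.
    """
    H = np.asarray(hg.incidence, dtype=float)
    w = np.asarray(hg.edge_weights, dtype=float)
    if H.ndim != 2 or w.shape != (H.shape[1],):
        raise HypergraphError("incidence / edge_weights shapes inconsistent")
    if not np.isin(H, (0.0, 1.0)).all():
        raise HypergraphError("incidence entries must be 0 or 1")
    if (w <= 0).any():
        raise HypergraphError("edge weights must be positive")

    edge_deg = H.sum(axis=0)
    if (edge_deg == 0).any():
        raise HypergraphError("every hyperedge must contain at least one vertex")
    vertex_deg = H @ w
    if (vertex_deg == 0).any():
        bad = np.flatnonzero(vertex_deg == 0)
        raise HypergraphError(
            f"isolated vertices {bad.tolist()}: increase k or prune these features"
        )

    S = (H * w / edge_deg) @ H.T
    S = 0.5 * (S + S.T)  # symmetrize against roundoff
    # dividing by sqrt(Dv_i * Dv_j) (rather than multiplying by the two
    # reciprocal roots) keeps simple rational cases exact in floating point
    S_norm = S / np.sqrt(np.outer(vertex_deg, vertex_deg))
    S_norm = 0.5 * (S_norm + S_norm.T)
    L = np.eye(H.shape[0]) - S_norm

    hg.edge_degrees = edge_deg
    hg.vertex_degrees = vertex_deg
    hg.similarity = S
    hg.normalized_similarity = S_norm
    hg.laplacian = L
    return hg


def build_knn_graph(profiles: np.ndarray, k: int = 2, metric: str = "euclidean") -> Hypergraph:
    """Simple mutualized KNN graph, as a 2-uniform hypergraph container.

    Edge i-j exists iff j is among i's ``k - 1`` nearest neighbors or vice
    versa (same k convention as :func:`build_knn_hypergraph`: k counts the
    vertex itself).  Returns a :class:`Hypergraph` whose ``similarity`` is
    the adjacency, with ``normalized_similarity = D^-1/2 A D^-1/2`` and
    ``L = I - D^-1/2 A D^-1/2``; the incidence matrix has one 2-vertex
    hyperedge per graph edge.  Used by the SNPLS baseline.
    """
    profiles = np.asarray(profiles, dtype=float)
    n_feat = profiles.shape[0]
    if not (1 <= k <= n_feat):
        raise HypergraphError(f"k={k} must satisfy 1 <= k <= n_features={n_feat}")
    z = _zscore_profiles(profiles)
    dist = cdist(z, z, metric="euclidean" if metric == "euclidean" else "correlation")

    adj = np.zeros((n_feat, n_feat))
    for j in range(n_feat):
        d = dist[j].copy()
        d[j] = np.inf
        order = np.argsort(d, kind="stable")
        adj[j, order[: k - 1]] = 1.0
    adj = np.maximum(adj, adj.T)  # mutualize

    deg = adj.sum(axis=1)
    if (deg == 0).any():
        # k=1 (or an isolated vertex): no coupling at all
        warnings.warn("graph has isolated vertices; their rows of L reduce to I", stacklevel=2)
    inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-300)), 0.0)
    S_norm = adj * np.outer(inv_sqrt, inv_sqrt)
    L = np.eye(n_feat) - S_norm

    ii, jj = np.nonzero(np.triu(adj, 1))
    H = np.zeros((n_feat, max(len(ii), 1)))
    if len(ii):
        H[ii, np.arange(len(ii))] = 1.0
        H[jj, np.arange(len(jj))] = 1.0
    else:
        H = np.eye(n_feat)  # placeholder incidence for the edgeless graph
    hg = Hypergraph(incidence=H, edge_weights=np.ones(H.shape[1]))
    hg.edge_degrees = H.sum(axis=0)
    hg.vertex_degrees = np.where(deg > 0, deg, 1.0)
    hg.similarity = adj
    hg.normalized_similarity = S_norm
    hg.laplacian = L
    # simple-graph normalized Laplacians have spectrum in [0, 2]; report the
    # excess over 1 so the solver's MM sweep stays a descent step
    hg.mm_shift = float(max(0.0, np.linalg.eigvalsh(L).max() - 1.0))
    return hg


def write_incidence_tsv(hg: Hypergraph, path) -> None:
    """Serialize H as sparse triplets (vertex_id, edge_id, value)."""
    ii, jj = np.nonzero(hg.incidence)
    with open(path, "w") as fh:
        fh.write("vertex_id\tedge_id\tvalue\n")
        for i, j in zip(ii, jj):
            fh.write(f"{i}\t{j}\t{hg.incidence[i, j]:g}\n")
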