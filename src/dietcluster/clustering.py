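"""Clustering of the exposure *variables* and representative selection.

The object of interest is not the participants but the 45 exposure columns:
two exposures are close when their z-scaled columns are close in Euclidean
distance, which for columns with zero mean and unit population SD reduces
to ``d_ij^2 = 2 n (1 - r_ij)`` with ``r`` the Pearson correlation and ``n``
the number of participants.  The variables are embedded exactly (classical
multidimensional scaling via SVD of the column matrix) into at most
``min(n, p) - 1`` dimensions, after which k-means, a BIC scan over k, a
small battery of cluster-number indices, hierarchical clustering, silhouette
computation and representative/second-hit selection all operate on those
points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .diaries import ExposureMatrix
from .exceptions import ConfigurationError, InputError


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------

@dataclass
class VariableEmbedding:
    """Exact Euclidean embedding of the exposure variables.

    ``coords`` has one row per variable; pairwise row distances equal the
    distances between the corresponding z-scaled data columns.
    """

    names: list[str]
    coords: np.ndarray  # (p, d)
    n_participants: int

    @property
    def n_variables(self) -> int:
        return len(self.names)

    def distance_matrix(self) -> np.ndarray:
        return cdist(self.coords, self.coords)


def embed_variables(matrix: ExposureMatrix | pd.DataFrame) -> VariableEmbedding:
    """Embed the transformed exposure columns as points.

    Accepts the full 45-variable :class:`ExposureMatrix` (transformed) or
    any participants x variables DataFrame of z-scaled columns.  Uses the
    thin SVD of the column-centred matrix ``X = U S V^T``; the rows of
    ``V S`` reproduce all pairwise column distances exactly while dropping
    the dimension to the matrix rank.
    """
    if isinstance(matrix, ExposureMatrix):
        if matrix.transformed is None:
            raise InputError(
                "embed_variables needs a transformed matrix; call transform_exposures first"
            )
        frame = matrix.transformed
    else:
        frame = matrix
    X = frame.to_numpy(dtype=float)
    n, p = X.shape
    if p < 2:
        raise InputError("need at least 2 variables to embed")
    if n < 2:
        raise InputError("need at least 2 participants to embed")
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    coords = vt.T * s  # (p, min(n, p)); row distances = column distances
    # centre the point configuration (distances are translation-invariant)
    # and drop null directions, giving dimension <= p - 1
    coords = coords - coords.mean(axis=0)
    _, s2, vt2 = np.linalg.svd(coords, full_matrices=False)
    keep = s2 > max(s2[0], 1.0) * 1e-12
    coords = coords @ vt2[keep].T
    return VariableEmbedding(names=list(frame.columns), coords=coords, n_participants=n)


# ---------------------------------------------------------------------------
# k-means and model selection
# ---------------------------------------------------------------------------

@dataclass
class ClusterSolution:
    """A k-means partition of the variables with quality annotations."""

    k: int
    assignment: pd.Series  # variable name -> cluster id (0..k-1)
    centroids: np.ndarray
    wcss: float
    bic: float
    silhouettes: pd.Series | None = None
    representatives: dict[int, str] = field(default_factory=dict)
    second_hits: pd.DataFrame | None = None  # cluster, variable, corr_with_top, retained

    def members(self, cluster: int) -> list[str]:
        return list(self.assignment.index[self.assignment == cluster])


def kmeans_bic(wcss: float, n: int, d: int, k: int) -> float:
    """Spherical-Gaussian BIC for a k-means partition of n points in d dims.

    ``BIC = n d ln(WCSS / (n d)) + k d ln(n)``; lower is better.  WCSS is
    floored at machine epsilon so a perfect partition stays finite.
    """
    wcss = max(wcss, np.finfo(float).eps)
    return n * d * np.log(wcss / (n * d)) + k * d * np.log(n)


def kmeans_fit(
    embedding: VariableEmbedding,
    k: int,
    n_restarts: int = 100,
    seed: int | None = 0,
) -> ClusterSolution:
    """Best-of-``n_restarts`` Lloyd k-means on the embedded variables.

    k-means++ seeding; the restart with the lowest within-cluster sum of
    squares wins; deterministic for a given seed.
    """
    p, d = embedding.coords.shape
    if not 1 <= k <= p:
        raise ConfigurationError(f"k must lie in [1, {p}], got {k}")
    km = KMeans(
        n_clusters=k,
        n_init=n_restarts,
        init="k-means++",
        algorithm="lloyd",
        random_state=seed,
    ).fit(embedding.coords)
    assignment = pd.Series(km.labels_, index=embedding.names, name="cluster")
    return ClusterSolution(
        k=k,
        assignment=assignment,
        centroids=km.cluster_centers_,
        wcss=float(km.inertia_),
        bic=kmeans_bic(float(km.inertia_), p, d, k),
    )


@dataclass
class BICScan:
    """BIC per candidate k and the minimizing k (ties -> smallest k)."""

    table: pd.DataFrame  # k, wcss, bic
    chosen_k: int
    solutions: dict[int, ClusterSolution]


def bic_scan(
    embedding: VariableEmbedding,
    k_range: tuple[int, int] = (1, 10),
    n_restarts: int = 100,
    seed: int | None = 0,
) -> BICScan:
    """Fit k-means across ``k_range`` (inclusive) and pick the lowest-BIC k."""
    lo, hi = k_range
    if not 1 <= lo <= hi <= embedding.n_variables:
        raise ConfigurationError(f"k_range {k_range} outside [1, {embedding.n_variables}]")
    sols = {k: kmeans_fit(embedding, k, n_restarts, seed) for k in range(lo, hi + 1)}
    table = pd.DataFrame(
        {"k": list(sols), "wcss": [s.wcss for s in sols.values()], "bic": [s.bic for s in sols.values()]}
    )
    chosen = int(table.loc[table["bic"].idxmin(), "k"])  # idxmin: first minimum -> smallest k
    return BICScan(table=table, chosen_k=chosen, solutions=sols)


# ---------------------------------------------------------------------------
# alternative cluster-number indices
# ---------------------------------------------------------------------------

IMPLEMENTED_INDICES = ("calinski_harabasz", "silhouette", "hartigan", "davies_bouldin", "gap")


def _gap_statistic(
    X: np.ndarray, labels_per_k: dict[int, np.ndarray], wcss_per_k: dict[int, float],
    n_ref: int = 10, seed: int = 0,
) -> int:
    """Gap statistic with uniform-box reference sets (reduced replicates).

    Chooses the smallest k with ``gap(k) >= gap(k+1) - s(k+1)``.
    """
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    ks = sorted(wcss_per_k)
    log_w_ref = {k: np.empty(n_ref) for k in ks}
    for b in range(n_ref):
        ref = rng.uniform(lo, hi, size=X.shape)
        for k in ks:
            km = KMeans(n_clusters=k, n_init=5, random_state=int(rng.integers(2**31))).fit(ref)
            log_w_ref[k][b] = np.log(max(km.inertia_, np.finfo(float).eps))
    gap, s = {}, {}
    for k in ks:
        lw = np.log(max(wcss_per_k[k], np.finfo(float).eps))
        gap[k] = log_w_ref[k].mean() - lw
        s[k] = log_w_ref[k].std(ddof=1) * np.sqrt(1 + 1 / n_ref)
    for k in ks[:-1]:
        if gap[k] >= gap[k + 1] - s[k + 1]:
            return k
    return ks[-1]


def index_vote(
    embedding: VariableEmbedding,
    k_range: tuple[int, int] = (2, 10),
    index_names: tuple[str, ...] = IMPLEMENTED_INDICES,
    n_restarts: int = 20,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Optimal-k vote from a battery of classical cluster-number indices.

    Returns one row per index with its preferred k.  All indices score the
    same best-of-restarts k-means partitions.  ``k_range`` must start at
    k >= 2 (the indices are undefined for a single cluster).
    """
    unknown = set(index_names) - set(IMPLEMENTED_INDICES)
    if unknown:
        raise ConfigurationError(f"unknown index names: {sorted(unknown)}")
    if not index_names:
        return pd.DataFrame(columns=["index", "optimal_k"])
    lo, hi = k_range
    if lo < 2:
        raise ConfigurationError("index_vote needs k_range starting at 2 or more")
    X = embedding.coords
    sols = {k: kmeans_fit(embedding, k, n_restarts, seed) for k in range(lo, hi + 1)}
    labels = {k: s.assignment.to_numpy() for k, s in sols.items()}
    wcss = {k: s.wcss for k, s in sols.items()}

    votes = {}
    ks = list(sols)
    if "calinski_harabasz" in index_names:
        sc = {k: calinski_harabasz_score(X, labels[k]) for k in ks}
        votes["calinski_harabasz"] = max(sc, key=sc.get)
    if "silhouette" in index_names:
        sc = {k: silhouette_score(X, labels[k]) for k in ks}
        votes["silhouette"] = max(sc, key=sc.get)
    if "davies_bouldin" in index_names:
        sc = {k: davies_bouldin_score(X, labels[k]) for k in ks}
        votes["davies_bouldin"] = min(sc, key=sc.get)
    if "hartigan" in index_names:
        # smallest k whose Hartigan statistic drops to <= 10
        n = X.shape[0]
        chosen = ks[-1]
        for k in ks[:-1]:
            h = (wcss[k] / max(wcss[k + 1], np.finfo(float).eps) - 1) * (n - k - 1)
            if h <= 10:
                chosen = k
                break
        votes["hartigan"] = chosen
    if "gap" in index_names:
        votes["gap"] = _gap_statistic(X, labels, wcss, seed=0 if seed is None else seed)

    rows = [{"index": name, "optimal_k": int(votes[name])} for name in index_names]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Agglomerative merge tree over the variables."""

    names: list[str]
    linkage_matrix: np.ndarray
    method: str

    def cut(self, k: int) -> pd.Series:
        labels = hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return pd.Series(labels - 1, index=self.names, name="cluster")

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def rec(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"'{self.names[node.id]}':{length:.10g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


def hierarchical_cluster(
    matrix: ExposureMatrix | pd.DataFrame, linkage: str = "complete"
) -> Dendrogram:
    """Agglomerative clustering of the variables on column distances."""
    emb = embed_variables(matrix)
    Z = hierarchy.linkage(emb.coords, method=linkage)
    return Dendrogram(names=emb.names, linkage_matrix=Z, method=linkage)


# ---------------------------------------------------------------------------
# silhouettes and representative selection
# ---------------------------------------------------------------------------

def silhouette_values(
    embedding: VariableEmbedding,
    assignment: pd.Series,
    method: str = "classical",
) -> pd.Series:
    """Per-variable silhouette in [-1, 1].

    ``classical``: s(i) = (b - a) / max(a, b) with ``a`` the mean distance
    to the other members of i's cluster and ``b`` the smallest mean
    distance to another cluster's members.  ``centroid``: the same ratio
    computed from distances to cluster centroids instead of members.
    Members of singleton clusters score 0 by convention.
    """
    labels = assignment.reindex(embedding.names).to_numpy()
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise InputError("silhouettes need at least 2 clusters")
    D = embedding.distance_matrix()
    p = len(labels)
    s = np.zeros(p)
    if method == "classical":
        for i in range(p):
            own = labels == labels[i]
            n_own = own.sum()
            if n_own == 1:
                continue
            a = D[i, own].sum() / (n_own - 1)
            b = min(D[i, labels == c].mean() for c in uniq if c != labels[i])
            s[i] = (b - a) / max(a, b)
    elif method == "centroid":
        cents = np.vstack([embedding.coords[labels == c].mean(axis=0) for c in uniq])
        dc = np.sqrt(
            ((embedding.coords[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
        )
        for i in range(p):
            ci = np.flatnonzero(uniq == labels[i])[0]
            if (labels == labels[i]).sum() == 1:
                continue
            a = dc[i, ci]
            b = min(dc[i, j] for j in range(len(uniq)) if j != ci)
            s[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    else:
        raise ConfigurationError(f"unknown silhouette method {method!r}")
    return pd.Series(s, index=embedding.names, name="silhouette")


def select_representatives(
    solution: ClusterSolution,
    correlations: pd.DataFrame,
    correlation_cutoff: float = 0.50,
) -> ClusterSolution:
    """Pick each cluster's representative and decide second-hit retention.

    The representative is the member with the highest silhouette (ties
    broken towards the lexicographically smaller name).  The member with
    the second-highest silhouette is retained as an additional exposure
    exactly when the absolute Pearson correlation between the two (on the
    transformed columns) is below ``correlation_cutoff``.
    """
    if solution.silhouettes is None:
        raise InputError("solution has no silhouettes; compute silhouette_values first")
    reps: dict[int, str] = {}
    rows = []
    for c in sorted(solution.assignment.unique()):
        members = solution.members(c)
        sil = solution.silhouettes.loc[members]
        order = pd.DataFrame({"s": sil, "name": sil.index}).sort_values(
            ["s", "name"], ascending=[False, True]
        )
        top = order.index[0]
        reps[int(c)] = top
        if len(order) >= 2:
            second = order.index[1]
            r = float(correlations.loc[top, second])
            rows.append(
                {
                    "cluster": int(c),
                    "variable": second,
                    "corr_with_top": r,
                    "retained": bool(abs(r) < correlation_cutoff),
                }
            )
    solution.representatives = reps
    solution.second_hits = pd.DataFrame(
        rows, columns=["cluster", "variable", "corr_with_top", "retained"]
    )
    return solution


def selected_exposures(solution: ClusterSolution) -> list[str]:
    """Representatives plus retained second hits, in cluster order."""
    out = []
    for c in sorted(solution.representatives):
        out.append(solution.representatives[c])
        if solution.second_hits is not None:
            hit = solution.second_hits[
                (solution.second_hits["cluster"] == c) & solution.second_hits["retained"]
            ]
            out.extend(hit["variable"].tolist())
    return out
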