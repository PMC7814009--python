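"""Population structure: distances, neighbor-joining trees, PCA, k-means.

All operations act on the samples x sites dosage matrix. With missing
genotypes, distances use pairwise-complete sites and PCA uses per-site
mean imputation before centering.

The neighbor-joining implementation is the classical Saitou-Nei
agglomeration with the Q-criterion, deterministic lowest-index
tie-breaking, and negative branch lengths clamped to zero for output
(raw values retained) -- exact on additive distance matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.cluster import KMeans

from .variants import MISSING, GenotypeMatrix

__all__ = [
    "DistanceMatrix",
    "UnrootedTree",
    "PcaResult",
    "pairwise_distance",
    "nj_tree",
    "pca",
    "kmeans_row_aggregate",
]


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be nonnegative")
        self.values = v


def pairwise_distance(
    matrix: GenotypeMatrix, metric: str = "euclidean"
) -> DistanceMatrix:
    """Pairwise distances between sample dosage vectors.

    manhattan: sum of |dosage differences| -- the total allele-count
    difference, so one dosage unit at one site contributes 1. euclidean:
    the L2 norm of the same difference vector. Sites with a missing call
    in either member of a pair are dropped for that pair.
    """
    if metric not in ("euclidean", "manhattan"):
        raise ValueError(f"unknown metric {metric!r}")
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples")
    d = matrix.dosage.astype(float)
    obs = matrix.dosage != MISSING
    n = matrix.n_samples
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = obs[i] & obs[j]
            diff = np.abs(d[i, ok] - d[j, ok])
            if metric == "manhattan":
                val = diff.sum()
            else:
                val = np.sqrt((diff**2).sum())
            out[i, j] = out[j, i] = val
    return DistanceMatrix(sample_ids=list(matrix.sample_ids), values=out)


@dataclass
class UnrootedTree:
    """NJ result: Newick text plus raw (pre-clamp) branch lengths."""

    newick: str
    leaf_ids: list[str]
    raw_branch_lengths: dict[str, float] = field(default_factory=dict)
    n_clamped: int = 0


def _newick_join(left: str, llen: float, right: str, rlen: float) -> str:
    return f"({left}:{max(llen, 0.0):.10g},{right}:{max(rlen, 0.0):.10g})"


def nj_tree(dist: DistanceMatrix) -> UnrootedTree:
    """Neighbor joining (Saitou-Nei) on a symmetric distance matrix.

    Ties in the Q-criterion break on the lowest (i, j) index pair of the
    current working matrix, so the output is deterministic. The final
    three nodes are joined at an internal (trifurcating, unrooted) node.
    """
    n = len(dist.sample_ids)
    if n < 3:
        raise ValueError("need at least 3 samples for a tree")
    d = dist.values.copy()
    labels = [f"{lid}" for lid in dist.sample_ids]
    nodes = [str(lab) for lab in labels]  # newick fragments
    raw: dict[str, float] = {}
    n_clamped = 0
    active = list(range(n))

    def record(name: str, length: float) -> float:
        nonlocal n_clamped
        raw[name] = length
        if length < 0:
            n_clamped += 1
        return max(length, 0.0)

    next_id = n
    names = list(labels)
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        q = (m - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        flat = np.argmin(q)  # first occurrence = lowest (i, j) in row order
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (totals[ai] - totals[aj]) / (2 * (m - 2))
        lj = dij - li
        li_c = record(f"{names[i]}", li)
        lj_c = record(f"{names[j]}", lj)
        new_name = f"node{next_id}"
        next_id += 1
        new_frag = f"({nodes[i]}:{li_c:.10g},{nodes[j]}:{lj_c:.10g})"
        # distances from the new node to the remaining ones
        new_row = np.zeros(d.shape[0] + 1)
        for ak in active:
            if ak in (i, j):
                continue
            new_row[ak] = 0.5 * (d[i, ak] + d[j, ak] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(new_frag)
        names.append(new_name)
        active = [a for a in active if a not in (i, j)] + [d.shape[0] - 1]

    # three-point closed form for the terminal join
    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    li_c = record(names[i], li)
    lj_c = record(names[j], lj)
    lk_c = record(names[k], lk)
    newick = (
        f"({nodes[i]}:{li_c:.10g},{nodes[j]}:{lj_c:.10g},{nodes[k]}:{lk_c:.10g});"
    )
    return UnrootedTree(
        newick=newick,
        leaf_ids=list(dist.sample_ids),
        raw_branch_lengths=raw,
        n_clamped=n_clamped,
    )


@dataclass
class PcaResult:
    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # sites x components
    variance_explained: np.ndarray
    means: np.ndarray  # per-site centering means


def pca(matrix: GenotypeMatrix | np.ndarray, n_components: int | None = None) -> PcaResult:
    """PCA of the dosage matrix via SVD.

    Column-mean centering only (no unit-variance scaling); missing values
    are mean-imputed per site before centering. Scores are returned for
    min(samples - 1, sites) components. Sign convention: the largest-
    magnitude loading of each component is positive.
    """
    x = matrix.dosage.astype(float) if isinstance(matrix, GenotypeMatrix) else np.asarray(matrix, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    miss = x == MISSING
    if miss.any():
        x = x.copy()
        col_means = np.where(
            (~miss).sum(axis=0) > 0,
            np.nanmean(np.where(miss, np.nan, x), axis=0),
            0.0,
        )
        x[miss] = np.broadcast_to(col_means, x.shape)[miss]
    means = x.mean(axis=0)
    xc = x - means
    max_comp = min(x.shape[0] - 1, x.shape[1])
    if n_components is None:
        n_components = max_comp
    n_components = min(n_components, max_comp)

    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    total_var = float((s**2).sum())
    if total_var == 0:
        warnings.warn("all-constant matrix: zero-variance PCA result", stacklevel=2)
        return PcaResult(
            scores=np.zeros((x.shape[0], n_components)),
            loadings=np.zeros((x.shape[1], n_components)),
            variance_explained=np.zeros(n_components),
            means=means,
        )
    # fix signs so the largest-magnitude loading in each component is positive
    for k in range(len(s)):
        peak = np.argmax(np.abs(vt[k]))
        if vt[k, peak] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    scores = (u * s)[:, :n_components]
    loadings = vt[:n_components].T
    var_exp = (s[:n_components] ** 2) / total_var
    return PcaResult(
        scores=scores,
        loadings=loadings,
        variance_explained=var_exp,
        means=means,
    )


def kmeans_row_aggregate(
    matrix: GenotypeMatrix | np.ndarray,
    k: int = 200,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate sites into k centroid rows for heatmap display.

    Sites (rows of the sites x samples view) are clustered with k-means
    (k-means++ init, one run, max 100 iterations, fixed seed); centroid
    values are the average dosage per site cluster. Centroid rows are
    ordered by hierarchical clustering for display. Returns (centroids
    (k x samples), per-site cluster assignment with centroid order
    applied).
    """
    x = matrix.dosage.astype(float).T if isinstance(matrix, GenotypeMatrix) else np.asarray(matrix, dtype=float)
    n_sites = x.shape[0]
    if k > n_sites:
        raise ValueError(f"k={k} exceeds number of sites {n_sites}")
    if k == n_sites:
        order = np.arange(n_sites)
        return x.copy(), order
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, max_iter=100, random_state=seed)
    assignment = km.fit_predict(x)
    centroids = km.cluster_centers_
    if k > 2:
        order = leaves_list(linkage(centroids, method="average"))
    else:
        order = np.arange(k)
    rank = np.empty(k, dtype=int)
    rank[order] = np.arange(k)
    return centroids[order], rank[assignment]
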