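"""Low-dimensional embeddings and hierarchical clustering of distance
matrices.

Classical (Torgerson) MDS double-centers the squared distance matrix,
B = -1/2 J D^2 J, and takes the top eigenpairs as coordinates; negative
eigenvalues (non-Euclidean input) are truncated at zero and reported.
SMACOF refines an embedding by Guttman-transform majorization of the raw
stress sum over pairs of (d_ij - dhat_ij)^2, which is non-increasing at
every iteration by construction.

Clustering is agglomerative (Lance-Williams recurrence via scipy; Ward by
default) over the full distance matrix, retaining the whole merge tree so
every level k can be inspected. Level quality is scored by the pseudo-F
(Calinski-Harabasz) statistic computed directly from distances:
    W = sum_c (1/n_c) sum_{i<j in c} d_ij^2,   T = (1/n) sum_{i<j} d_ij^2,
    B = T - W,   pseudoF(k) = (B/(k-1)) / (W/(n-k)).
W = 0 at some level means perfectly tight clusters; the profile flags it
as infinite rather than erroring. The selection of k is reported (all local
maxima plus the global maximum), never auto-committed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.linalg import eigh

from .datatypes import DistanceMatrix


@dataclass
class Embedding:
    ids: list[str]
    coords: np.ndarray  # n x dims
    stress: float
    method: str
    eigenvalues: np.ndarray | None = None
    n_negative_eigenvalues: int = 0
    n_iter: int = 0

    def pairwise_distances(self) -> np.ndarray:
        from scipy.spatial.distance import pdist, squareform

        return squareform(pdist(self.coords))


def _as_dense(D: DistanceMatrix | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(D, DistanceMatrix):
        if D.is_similarity:
            D = D.to_distance()
        if D.has_missing():
            raise ValueError(
                "distance matrix has missing pairs; lower min_overlap or drop "
                "the affected samples before embedding/clustering"
            )
        return D.values, list(D.ids)
    arr = np.asarray(D, dtype=float)
    return arr, [str(i) for i in range(arr.shape[0])]


def raw_stress(D: np.ndarray, coords: np.ndarray) -> float:
    """Sum over unordered pairs of (d_ij - dhat_ij)^2."""
    from scipy.spatial.distance import pdist

    iu = np.triu_indices(len(coords), k=1)
    return float(((D[iu] - pdist(coords)) ** 2).sum())


def classical_mds(D: DistanceMatrix | np.ndarray, dims: int = 3) -> Embedding:
    """Torgerson scaling: eigendecomposition of the double-centered squared
    distance matrix. Exact for distances embeddable in ``dims`` dimensions."""
    dmat, ids = _as_dense(D)
    n = dmat.shape[0]
    if not np.all(np.isfinite(dmat)):
        raise ValueError("non-finite distances")
    d2 = dmat**2
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ d2 @ J
    B = 0.5 * (B + B.T)
    vals, vecs = eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    n_neg = int((vals < -1e-9 * max(abs(vals[0]), 1.0)).sum())
    top = vals[:dims]
    coords = vecs[:, :dims] * np.sqrt(np.maximum(top, 0.0))[None, :]
    return Embedding(
        ids,
        coords,
        stress=raw_stress(dmat, coords),
        method="classical",
        eigenvalues=vals,
        n_negative_eigenvalues=n_neg,
    )


def smacof_mds(
    D: DistanceMatrix | np.ndarray,
    dims: int = 3,
    init: np.ndarray | str = "classical",
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int | None = None,
    return_history: bool = False,
) -> Embedding | tuple[Embedding, list[float]]:
    """SMACOF majorization of raw stress via the Guttman transform.

    ``init`` is 'classical' (default), 'random' (seeded), or an explicit
    n x dims array. Stops when the relative stress decrease falls below
    ``tol`` or after ``max_iter`` iterations; the per-iteration stress
    sequence is non-increasing and can be returned for inspection.
    """
    dmat, ids = _as_dense(D)
    n = dmat.shape[0]
    if not np.all(np.isfinite(dmat)):
        raise ValueError("non-finite distances")
    if isinstance(init, str):
        if init == "classical":
            x = classical_mds(dmat, dims=dims).coords.copy()
        elif init == "random":
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(n, dims))
        else:
            raise ValueError(f"unknown init {init!r}")
    else:
        x = np.array(init, dtype=float)
        if x.shape != (n, dims):
            raise ValueError("init coordinates have the wrong shape")

    stress = raw_stress(dmat, x)
    history = [stress]
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # Guttman transform: X <- (1/n) B(X) X with B from the ratio d/dhat
        from scipy.spatial.distance import pdist, squareform

        dhat = squareform(pdist(x))
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(dhat > 0, dmat / np.where(dhat > 0, dhat, 1.0), 0.0)
        np.fill_diagonal(ratio, 0.0)
        B = -ratio
        np.fill_diagonal(B, ratio.sum(axis=1))
        x = (B @ x) / n
        new_stress = raw_stress(dmat, x)
        history.append(new_stress)
        if stress > 0 and (stress - new_stress) / stress < tol:
            stress = new_stress
            break
        stress = new_stress
        if stress == 0.0:
            break

    emb = Embedding(ids, x, stress=stress, method="smacof", n_iter=n_iter)
    if return_history:
        return emb, history
    return emb


@dataclass
class ClusterTree:
    """Full agglomerative merge structure over n samples.

    ``linkage_matrix`` is the scipy (n-1) x 4 encoding; ``cut(k)`` yields
    the level-k partition as 0-based labels, and partitions are nested
    across levels by construction.
    """

    ids: list[str]
    linkage_matrix: np.ndarray
    linkage: str = "ward"

    @property
    def n(self) -> int:
        return len(self.ids)

    def cut(self, k: int) -> np.ndarray:
        if not (1 <= k <= self.n):
            raise ValueError(f"k must be in [1, {self.n}]")
        labels = hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return np.asarray(labels) - 1

    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def split_members(self, merge_index: int) -> tuple[np.ndarray, np.ndarray]:
        """Sample indices of the two daughter groups of a merge (counted
        from the final merge downward: 0 is the root split into 2 groups)."""
        row = self.linkage_matrix[self.n - 2 - merge_index]
        return (self._leaves(int(row[0])), self._leaves(int(row[1])))

    def _leaves(self, node: int) -> np.ndarray:
        if node < self.n:
            return np.array([node])
        stack, out = [node], []
        while stack:
            v = stack.pop()
            if v < self.n:
                out.append(v)
            else:
                row = self.linkage_matrix[v - self.n]
                stack.extend((int(row[0]), int(row[1])))
        return np.sort(np.array(out))


def hierarchical_tree(
    D: DistanceMatrix | np.ndarray, linkage: str = "ward"
) -> ClusterTree:
    """Agglomerative clustering of a distance matrix (Lance-Williams
    recurrence; ward default, average/complete/single available)."""
    dmat, ids = _as_dense(D)
    n = dmat.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")
    if linkage not in ("ward", "average", "complete", "single"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    iu = np.triu_indices(n, k=1)
    Z = hierarchy.linkage(dmat[iu], method=linkage)
    return ClusterTree(ids, Z, linkage)


@dataclass
class PseudoFProfile:
    ks: np.ndarray
    values: np.ndarray  # np.inf flags W = 0 levels
    selected_k: int = 0
    local_maxima: list[int] = field(default_factory=list)

    def as_dict(self) -> dict[int, float]:
        return {int(k): float(v) for k, v in zip(self.ks, self.values)}


def pseudo_f_statistic(D: np.ndarray, labels: np.ndarray) -> float:
    """Calinski-Harabasz ratio computed from squared distances alone."""
    n = len(labels)
    d2 = D**2
    iu = np.triu_indices(n, k=1)
    T = d2[iu].sum() / n
    W = 0.0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        W += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    B = max(T - W, 0.0)
    k = len(np.unique(labels))
    if k < 2 or k > n - 1:
        raise ValueError("pseudo-F defined for 2 <= k <= n-1")
    if W == 0.0:
        return np.inf
    return (B / (k - 1)) / (W / (n - k))


def pseudo_f_profile(
    D: DistanceMatrix | np.ndarray, tree: ClusterTree, k_max: int | None = None
) -> PseudoFProfile:
    """Pseudo-F across tree levels k = 2 .. min(k_max, n-1), with the global
    maximum and all local maxima reported for the analyst to judge."""
    dmat, _ = _as_dense(D)
    n = tree.n
    upper = n - 1 if k_max is None else min(k_max, n - 1)
    ks, vals = [], []
    for k in range(2, upper + 1):
        labels = tree.cut(k)
        if len(np.unique(labels)) != k:
            continue
        ks.append(k)
        vals.append(pseudo_f_statistic(dmat, labels))
    ks_arr = np.array(ks, dtype=int)
    vals_arr = np.array(vals, dtype=float)
    if len(vals_arr) == 0:
        return PseudoFProfile(ks_arr, vals_arr)
    finite = np.where(np.isfinite(vals_arr), vals_arr, np.nanmax(vals_arr[np.isfinite(vals_arr)]) * 10 if np.isfinite(vals_arr).any() else 1.0)
    best = int(ks_arr[int(np.argmax(vals_arr))])
    local = []
    for i in range(len(ks_arr)):
        left = finite[i - 1] if i > 0 else -np.inf
        right = finite[i + 1] if i < len(ks_arr) - 1 else -np.inf
        if finite[i] >= left and finite[i] >= right and (finite[i] > left or finite[i] > right):
            local.append(int(ks_arr[i]))
    return PseudoFProfile(ks_arr, vals_arr, selected_k=best, local_maxima=local)
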