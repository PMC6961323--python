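"""Drug clustering: bootstrap-stability model selection, k-means partition,
kernel diagnosis sets, inter-cluster hierarchy and 2-D embedding.

The number of clusters k is selected by cluster-wise bootstrap stability:
cluster the full cohort once (the reference partition), then repeatedly
resample drugs with replacement, re-cluster the resample, and score each
reference cluster by its best Jaccard membership overlap with any resample
cluster (restricted to drugs present in the resample).  The mean of these
overlaps over clusters and resamples is the stability of that k; the k with
the highest mean stability wins, smallest k on ties.

k-means operates on each drug's row of the Jaccard distance matrix
(distances-to-all-drugs as coordinates), the standard way to feed a
precomputed distance matrix to a centroid method.  A k-medoids-style
alternative (PAM on the raw distances) is available via ``method``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from ._seeds import derive_seed
from .distance import jaccard_distance


class DegenerateInputWarning(UserWarning):
    """Fewer distinct rows than requested clusters."""


@dataclass
class ClusteringConfig:
    """Knobs for k selection and partitioning.

    k_min..k_max is the candidate range (default 10..50), B the number of
    bootstrap resamples per candidate, n_init the k-means restarts, and
    kernel_min_share the fraction of member drugs a diagnosis must be
    associated with to enter a cluster's kernel set (0 = union).
    """

    k_min: int = 10
    k_max: int = 50
    B: int = 100
    seed: int = 0
    n_init: int = 10
    kernel_min_share: float = 0.0
    method: str = "kmeans"

    def validate(self, n_drugs: int) -> None:
        if not (2 <= self.k_min <= self.k_max < n_drugs):
            raise ValueError(
                f"need 2 <= k_min <= k_max < n_drugs; got "
                f"[{self.k_min}, {self.k_max}] with {n_drugs} drugs"
            )
        if self.B < 2:
            raise ValueError("need at least B=2 bootstrap resamples")


@dataclass
class DrugClustering:
    """A partition of drugs into k clusters with diagnostics.

    ``labels`` maps drug_code -> cluster id (1..k, every cluster nonempty);
    ``stability_profile`` holds the per-candidate mean bootstrap Jaccard
    index when k was selected; ``kernel_sets`` the per-cluster diagnosis
    sets once attached.
    """

    labels: pd.Series
    k: int
    stability: float | None = None
    stability_profile: pd.DataFrame | None = None
    kernel_sets: dict = field(default_factory=dict)

    def members(self, cluster_id: int) -> pd.Index:
        return self.labels.index[self.labels == cluster_id]

    @property
    def cluster_ids(self):
        return sorted(self.labels.unique())

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def _as_array(distmat: pd.DataFrame) -> np.ndarray:
    X = np.asarray(distmat, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] != X.shape[1]:
        raise ValueError("distance matrix must be square")
    return X


def _kmeans_labels(X: np.ndarray, k: int, seed: int, n_init: int) -> np.ndarray:
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed % (2**31))
    return km.fit_predict(X)


def _pam_labels(D: np.ndarray, k: int, seed: int, n_init: int) -> np.ndarray:
    """Plain PAM (partitioning around medoids) on the raw distances."""
    rng = np.random.default_rng(seed)
    n = D.shape[0]
    best_labels, best_cost = None, np.inf
    for _ in range(max(1, n_init)):
        medoids = rng.choice(n, size=k, replace=False)
        for _ in range(100):
            labels = np.argmin(D[:, medoids], axis=1)
            new_medoids = medoids.copy()
            for j in range(k):
                idx = np.flatnonzero(labels == j)
                if len(idx) == 0:
                    continue
                within = D[np.ix_(idx, idx)].sum(axis=1)
                new_medoids[j] = idx[np.argmin(within)]
            if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
                break
            medoids = new_medoids
        cost = D[np.arange(n), medoids[labels]].sum()
        if cost < best_cost:
            best_cost, best_labels = cost, labels
    return best_labels


def cluster_drugs(
    distmat: pd.DataFrame,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    method: str = "kmeans",
) -> DrugClustering:
    """Partition drugs into k clusters from the pairwise distance matrix.

    Deterministic for fixed (distmat, k, seed, n_init).  If the matrix has
    fewer distinct rows than k, a :class:`DegenerateInputWarning` is issued
    and identical rows are split arbitrarily but deterministically so the
    partition stays total with k nonempty clusters.
    """
    X = _as_array(distmat)
    n = X.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"need 2 <= k < n_drugs ({n}); got k={k}")
    n_distinct = len(np.unique(X, axis=0))
    if n_distinct < k:
        warnings.warn(
            f"only {n_distinct} distinct rows for k={k}; splitting ties "
            "deterministically",
            DegenerateInputWarning,
        )
        order = np.lexsort(X.T[::-1])
        raw = np.empty(n, dtype=int)
        raw[order] = np.arange(n) % k
    elif method == "kmeans":
        raw = _kmeans_labels(X, k, seed, n_init)
    elif method == "pam":
        raw = _pam_labels(X, k, seed, n_init)
    else:
        raise ValueError("method must be 'kmeans' or 'pam'")
    # relabel to consecutive 1..k_eff by order of first appearance
    _, raw = np.unique(raw, return_inverse=True)
    labels = pd.Series(raw + 1, index=distmat.index, name="cluster_id")
    k_eff = labels.nunique()
    if k_eff < k:
        warnings.warn(
            f"k-means produced {k_eff} nonempty clusters for k={k}",
            DegenerateInputWarning,
        )
    return DrugClustering(labels=labels, k=k_eff)


def bootstrap_stability(
    distmat: pd.DataFrame,
    k: int,
    B: int = 100,
    seed: int = 0,
    n_init: int = 10,
    method: str = "kmeans",
) -> float:
    """Mean cluster-wise bootstrap Jaccard stability of k clusters.

    For each of B resamples of drugs (with replacement) the resampled
    distance submatrix is re-clustered; each reference cluster scores its
    maximum Jaccard overlap, over resample clusters, between memberships
    restricted to the distinct drugs present in the resample.  Returns the
    mean over clusters and resamples, in [0, 1].
    """
    X = _as_array(distmat)
    n = X.shape[0]
    if B < 2:
        raise ValueError("need B >= 2")
    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        # candidate k values beyond the number of distinct rows are normal
        # during model selection; they just score poorly
        warnings.simplefilter("ignore", DegenerateInputWarning)
        warnings.simplefilter("ignore", ConvergenceWarning)
        ref = cluster_drugs(
            distmat, k, seed=derive_seed(seed, "ref"), n_init=n_init, method=method
        )
        ref_sets = [
            set(np.flatnonzero(ref.labels.to_numpy() == c)) for c in ref.cluster_ids
        ]
        rng = np.random.default_rng(derive_seed(seed, "bootstrap"))
        scores = []
        for b in range(B):
            idx = rng.integers(0, n, size=n)
            sub = X[np.ix_(idx, idx)]
            bs_seed = derive_seed(seed, "resample", b)
            if method == "kmeans":
                blab = _kmeans_labels(sub, k, bs_seed, n_init)
            else:
                blab = _pam_labels(sub, k, bs_seed, n_init)
            present = np.unique(idx)
            boot_sets = [
                set(np.unique(idx[blab == j])) for j in np.unique(blab)
            ]
            present_set = set(present.tolist())
            for members in ref_sets:
                restricted = members & present_set
                if not restricted:
                    continue
                best = max(
                    len(restricted & bs) / len(restricted | bs) for bs in boot_sets
                )
                scores.append(best)
    return float(np.mean(scores))


def select_k(
    distmat: pd.DataFrame, config: ClusteringConfig
) -> tuple[int, pd.DataFrame]:
    """Evaluate bootstrap stability over [k_min, k_max]; return the argmax
    (smallest k on ties) and the full stability profile."""
    config.validate(len(distmat))
    rows = []
    for k in range(config.k_min, config.k_max + 1):
        s = bootstrap_stability(
            distmat,
            k,
            B=config.B,
            seed=derive_seed(config.seed, "select_k", k),
            n_init=config.n_init,
            method=config.method,
        )
        rows.append((k, s))
    profile = pd.DataFrame(rows, columns=["k", "mean_jaccard"])
    best = profile.loc[profile["mean_jaccard"].idxmax(), "k"]  # idxmax: first max
    return int(best), profile


def kernel_diagnoses(
    clustering: DrugClustering,
    binmat: pd.DataFrame,
    min_share: float = 0.0,
) -> dict:
    """Per-cluster kernel diagnosis sets.

    A diagnosis enters cluster c's kernel when the fraction of c's member
    drugs significantly associated with it is >= min_share (and > 0);
    min_share=0 therefore gives the union over members, min_share=1 the
    intersection.  Clusters of unassociated drugs get empty kernels.
    """
    if not 0.0 <= min_share <= 1.0:
        raise ValueError("min_share must be in [0, 1]")
    kernels = {}
    for c in clustering.cluster_ids:
        members = clustering.members(c)
        share = binmat.loc[members].mean(axis=0)
        threshold = min_share if min_share > 0 else np.finfo(float).tiny
        kernels[c] = frozenset(share.index[share >= threshold])
    return kernels


def cluster_hierarchy(kernel_sets: dict, linkage: str = "average"):
    """Agglomerative hierarchy over clusters by kernel-set Jaccard distance.

    Returns ``(Z, cluster_ids)`` where Z is a scipy linkage matrix whose
    leaves are ``cluster_ids`` in order.
    """
    ids = sorted(kernel_sets)
    if len(ids) < 2:
        raise ValueError("need at least 2 clusters for a hierarchy")
    m = len(ids)
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            D[i, j] = D[j, i] = jaccard_distance(kernel_sets[ids[i]], kernel_sets[ids[j]])
    Z = _scipy_linkage(squareform(D, checks=False), method=linkage)
    return Z, ids


def hierarchy_to_newick(Z: np.ndarray, leaf_names) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    from scipy.cluster.hierarchy import to_tree

    tree = to_tree(Z)
    names = [str(x) for x in leaf_names]

    def _walk(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = _walk(node.left, node.dist)
        right = _walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return _walk(tree, tree.dist) + ";"


def embed_2d(distmat: pd.DataFrame) -> pd.DataFrame:
    """Classical multidimensional scaling to 2-D.

    Double-centers the squared distance matrix and takes the top two
    eigenvectors scaled by sqrt(eigenvalue); deterministic up to sign,
    which is fixed by making each axis's largest-magnitude loading
    positive.  Duplicate rows map to coincident points.
    """
    X = _as_array(distmat)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 drugs for a 2-D embedding")
    J = np.eye(n) - np.ones((n, n)) / n
    Bc = -0.5 * J @ (X**2) @ J
    Bc = (Bc + Bc.T) / 2
    vals, vecs = np.linalg.eigh(Bc)
    order = np.argsort(vals)[::-1][:2]
    coords = np.zeros((n, 2))
    for a, idx in enumerate(order):
        lam = max(vals[idx], 0.0)
        v = vecs[:, idx]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        coords[:, a] = v * np.sqrt(lam)
    return pd.DataFrame(coords, index=distmat.index, columns=["mds1", "mds2"])
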