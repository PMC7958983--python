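"""K-means subgroup discovery with restart selection and a permutation null.

Survivor profiles (rows of the 39-item response matrix, not the aggregated
type scores) are clustered with Euclidean K-means, taking the best of many
random restarts by total within-cluster distance.  The number of clusters
is chosen by the Calinski-Harabasz criterion over a K grid.  Subgroup
heterogeneity is the mean pairwise Euclidean distance among members, and
its null distribution comes from repeatedly sampling random survivor
groups of the same size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score

from .cohort import ResponseMatrix


def _as_array(matrix) -> np.ndarray:
    if isinstance(matrix, ResponseMatrix):
        return matrix.values.astype(float)
    return np.asarray(matrix, dtype=float)


@dataclass
class ClusteringResult:
    """Best-of-restarts K-means clustering, labels canonicalized by size."""

    k: int
    labels: np.ndarray
    centroids: np.ndarray
    inertia: float              # total within-cluster point-to-centroid distance
    restarts: int
    seed: int

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


def _canonicalize(labels: np.ndarray, centroids: np.ndarray, k: int):
    """Relabel clusters 0..k-1 by descending size (ties: original label)."""
    sizes = np.bincount(labels, minlength=k)
    order = sorted(range(k), key=lambda c: (-sizes[c], c))
    remap = np.empty(k, dtype=int)
    for new, old in enumerate(order):
        remap[old] = new
    return remap[labels], centroids[order]


def cluster(matrix, k: int, restarts: int = 100, seed: int = 0) -> ClusteringResult:
    """Euclidean K-means, best of ``restarts`` runs by within-cluster distance.

    Each restart is initialized with distance-weighted (k-means++) seeding,
    deterministic in ``seed``.  Cluster labels are canonicalized by
    descending cluster size so identical partitions always get identical
    labels.
    """
    x = _as_array(matrix)
    n = x.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n_survivors ({n}); got {k}")
    km = KMeans(n_clusters=k, n_init=restarts, init="k-means++", random_state=seed % (2**32))
    labels = km.fit_predict(x)
    labels, centroids = _canonicalize(labels, km.cluster_centers_, k)
    return ClusteringResult(
        k=k, labels=labels, centroids=centroids,
        inertia=float(km.inertia_), restarts=restarts, seed=seed,
    )


@dataclass
class KSelection:
    """Calinski-Harabasz model selection across a K grid."""

    k_star: int
    table: pd.DataFrame          # columns k, calinski_harabasz, inertia
    results: dict[int, ClusteringResult]


def select_k(matrix, k_range=range(2, 11), restarts: int = 100, seed: int = 0) -> KSelection:
    """Choose K by the Calinski-Harabasz index over ``k_range``.

    Returns the argmax along with the full index-vs-K table and the best
    clustering at each K.  All-identical data has no between-cluster
    variance and raises.
    """
    x = _as_array(matrix)
    if np.all(x == x[0]):
        raise ValueError("all survivor profiles are identical; K selection is undefined")
    rows, results = [], {}
    for k in k_range:
        res = cluster(x, k, restarts=restarts, seed=seed)
        ch = calinski_harabasz_score(x, res.labels)
        rows.append((k, ch, res.inertia))
        results[k] = res
    table = pd.DataFrame(rows, columns=["k", "calinski_harabasz", "inertia"])
    k_star = int(table.loc[table["calinski_harabasz"].idxmax(), "k"])
    return KSelection(k_star=k_star, table=table, results=results)


def heterogeneity(matrix, member_idx=None) -> float:
    """Mean pairwise Euclidean distance among a group of survivor profiles."""
    x = _as_array(matrix)
    if member_idx is not None:
        x = x[np.asarray(member_idx)]
    if x.shape[0] < 2:
        raise ValueError("heterogeneity requires a group of at least 2 survivors")
    return float(pdist(x, metric="euclidean").mean())


@dataclass
class HeterogeneityNull:
    """Permutation null of group heterogeneity as a function of group size.

    ``band`` is indexed by size with columns mean, lo (2.5th percentile)
    and hi (97.5th percentile) over ``n_perm`` random groups.
    """

    band: pd.DataFrame
    n_perm: int

    def flag(self, size: int, observed: float) -> str:
        """'below', 'within' or 'above' the null band at this group size."""
        row = self.band.loc[size]
        if observed < row["lo"]:
            return "below"
        if observed > row["hi"]:
            return "above"
        return "within"


def permutation_null(
    matrix, sizes, n_perm: int = 100, seed: int = 0
) -> HeterogeneityNull:
    """Null heterogeneity band from random survivor groups of each size.

    For each size, draws ``n_perm`` uniform without-replacement samples of
    survivors and records the mean and empirical 2.5/97.5 percentiles of
    their heterogeneity.
    """
    x = _as_array(matrix)
    n = x.shape[0]
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        size = int(size)
        if size < 2:
            raise ValueError(f"group size must be >= 2, got {size}")
        if size > n:
            raise ValueError(f"group size {size} exceeds cohort size {n}")
        vals = np.empty(n_perm)
        for b in range(n_perm):
            idx = rng.choice(n, size=size, replace=False)
            vals[b] = pdist(x[idx]).mean()
        rows.append((size, vals.mean(), *np.percentile(vals, [2.5, 97.5])))
    band = pd.DataFrame(rows, columns=["size", "mean", "lo", "hi"]).set_index("size")
    return HeterogeneityNull(band=band, n_perm=n_perm)


def subgroup_profiles(scores: pd.DataFrame, result: ClusteringResult) -> pd.DataFrame:
    """Five-number summaries of the type scores within each cluster.

    Returns a long DataFrame with one row per (cluster, type): n, median,
    q1, q3, min, max.  Empty clusters are skipped with a warning.
    """
    if len(scores) != len(result.labels):
        raise ValueError("scores and clustering cover different numbers of survivors")
    rows = []
    for c in range(result.k):
        sel = result.labels == c
        if not sel.any():
            warnings.warn(f"cluster {c} is empty; skipped", stacklevel=2)
            continue
        sub = scores.loc[sel]
        for t in scores.columns:
            v = sub[t]
            rows.append(
                (c, t, int(sel.sum()), v.median(), v.quantile(0.25),
                 v.quantile(0.75), v.min(), v.max())
            )
    return pd.DataFrame(
        rows, columns=["cluster", "type", "n", "median", "q1", "q3", "min", "max"]
    )
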