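"""Behavioural subtype discovery on the four cueing-effect features.

Features (one spatial-certainty effect and three incentive-value effects
per subject) are z-scored, screened for multivariate outliers by squared
Mahalanobis distance, and clustered two ways: a k-means sweep over k = 1..10
(best of many random initialisations per k) whose solution is selected by
the largest relative within-SS drop, the mean silhouette width and the Dunn
index; and OPTICS, whose reachability profile separates one-or-more dense
clusters from outliers, with minimum cluster membership set to the number
of features plus one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist, pdist
from sklearn.cluster import OPTICS, KMeans, cluster_optics_dbscan
from sklearn.metrics import silhouette_score

__all__ = [
    "ClusterSolution",
    "dunn_index",
    "kmeans_sweep",
    "mahalanobis_screen",
    "optics_cluster",
    "scale_features",
    "select_solution",
]


@dataclass
class ClusterSolution:
    """Outcome of one clustering algorithm.

    For k-means: per-k diagnostics and labels for every k in the sweep.
    For OPTICS: one label vector (-1 = outlier) plus the reachability
    ordering and distances.
    """

    algorithm: str
    labels: np.ndarray | None = None
    labels_by_k: dict[int, np.ndarray] = field(default_factory=dict)
    within_ss: dict[int, float] = field(default_factory=dict)
    silhouette: dict[int, float] = field(default_factory=dict)
    dunn: dict[int, float] = field(default_factory=dict)
    ordering: np.ndarray | None = None
    reachability: np.ndarray | None = None
    min_samples: int | None = None

    def diagnostics_frame(self) -> pd.DataFrame:
        ks = sorted(self.within_ss)
        return pd.DataFrame(
            {
                "k": ks,
                "within_ss": [self.within_ss[k] for k in ks],
                "silhouette": [self.silhouette.get(k, np.nan) for k in ks],
                "dunn": [self.dunn.get(k, np.nan) for k in ks],
            }
        )


def _as_matrix(features) -> tuple[np.ndarray, list[str]]:
    if isinstance(features, pd.DataFrame):
        cols = [c for c in features.columns if c != "subject"]
        return features[cols].to_numpy(dtype=float), cols
    arr = np.asarray(features, dtype=float)
    return arr, [f"f{i}" for i in range(arr.shape[1])]


def scale_features(features):
    """Z-score each feature across subjects (sample sd, ddof = 1).

    Idempotent up to floating point. A zero-variance feature cannot be
    scaled and raises, naming the column.
    """
    mat, cols = _as_matrix(features)
    if mat.shape[0] < 2:
        raise ValueError("scaling needs at least 2 subjects")
    if not np.all(np.isfinite(mat)):
        raise ValueError("features must be finite")
    sd = mat.std(axis=0, ddof=1)
    dead = [cols[i] for i in np.flatnonzero(sd == 0)]
    if dead:
        raise ValueError(f"zero-variance feature(s): {dead}")
    scaled = (mat - mat.mean(axis=0)) / sd
    if isinstance(features, pd.DataFrame):
        out = features.copy()
        out[cols] = scaled
        return out
    return scaled


def mahalanobis_screen(
    features, threshold: float | None = None, alpha: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Squared Mahalanobis distance to the feature mean; flag extremes.

    Default threshold is the chi-square (1 - alpha) quantile with
    df = number of features, applied to the squared distances; pass a raw
    ``threshold`` to override (e.g. to reproduce a published fixed cut).
    Requires more subjects than features and an invertible covariance.
    """
    mat, _ = _as_matrix(features)
    n, p = mat.shape
    if n <= p:
        raise ValueError("need more subjects than features")
    cov = np.cov(mat, rowvar=False, ddof=1)
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular feature covariance") from exc
    centred = mat - mat.mean(axis=0)
    d2 = np.einsum("ij,jk,ik->i", centred, cov_inv, centred)
    if threshold is None:
        threshold = float(stats.chi2.ppf(1.0 - alpha, df=p))
    return d2 > threshold, d2


def dunn_index(scaled, labels) -> float:
    """Minimum between-cluster distance over maximum within-cluster diameter.

    Between-cluster distance is single linkage (closest pair across the two
    point sets); diameter is the largest pairwise distance within a
    cluster (0 for singletons). When every cluster is a singleton the
    diameter is 0 and the index is reported as +inf.
    """
    mat, _ = _as_matrix(scaled)
    labels = np.asarray(labels)
    ids = np.unique(labels)
    if len(ids) < 2:
        raise ValueError("Dunn index needs at least 2 clusters")
    groups = [mat[labels == i] for i in ids]
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty cluster")
    min_between = min(
        cdist(groups[i], groups[j]).min()
        for i in range(len(groups))
        for j in range(i + 1, len(groups))
    )
    max_diam = max(pdist(g).max() if len(g) > 1 else 0.0 for g in groups)
    if max_diam == 0.0:
        return float("inf")
    return float(min_between / max_diam)


def kmeans_sweep(
    scaled,
    k_range=range(1, 11),
    n_init: int = 1000,
    seed: int | np.random.Generator = 0,
) -> ClusterSolution:
    """Best-of-``n_init`` k-means for each k, with per-k diagnostics.

    Initialisation is plain random restarts (random points as centroids).
    ``within_ss`` is the within-cluster sum of squared Euclidean
    distances; silhouette and Dunn are recorded for k >= 2. k values
    exceeding n are skipped.
    """
    mat, _ = _as_matrix(scaled)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sol = ClusterSolution(algorithm="kmeans")
    n = mat.shape[0]
    for k in k_range:
        if k > n:
            continue
        km = KMeans(
            n_clusters=k,
            init="random",
            n_init=n_init,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(mat)
        sol.labels_by_k[k] = km.labels_.copy()
        sol.within_ss[k] = float(km.inertia_)
        if 2 <= k < n and len(np.unique(km.labels_)) > 1:
            sol.silhouette[k] = float(silhouette_score(mat, km.labels_))
            sol.dunn[k] = dunn_index(mat, km.labels_)
    if not sol.within_ss:
        raise ValueError("no k in range was feasible")
    return sol


def optics_cluster(
    scaled,
    min_samples: int | None = None,
    method: str = "reachability",
    xi: float = 0.05,
    eps: float | None = None,
    eps_factor: float = 1.8,
) -> ClusterSolution:
    """OPTICS reachability clustering with outlier extraction.

    ``min_samples`` defaults to the number of features plus 1. Default
    extraction cuts the reachability profile at a threshold: points whose
    reachability exceeds ``eps`` fall outside every cluster and are
    labelled -1 (outliers). When ``eps`` is not given it is set to
    ``eps_factor`` times the median finite reachability, which places the
    cut above the dense main body but below the discontinuity that
    separates sparse points. ``method='xi'`` uses steepness-based
    extraction instead (sensitive to small relative fluctuations on
    cohort-sized samples, hence not the default).
    """
    mat, _ = _as_matrix(scaled)
    n, p = mat.shape
    if min_samples is None:
        min_samples = p + 1
    if n <= min_samples:
        raise ValueError(f"need more than min_samples={min_samples} points, got {n}")
    if method == "xi":
        opt = OPTICS(
            min_samples=min_samples, cluster_method="xi", xi=xi, min_cluster_size=min_samples
        ).fit(mat)
        labels = opt.labels_.copy()
    elif method == "reachability":
        opt = OPTICS(min_samples=min_samples).fit(mat)
        if eps is None:
            finite = opt.reachability_[np.isfinite(opt.reachability_)]
            eps = float(eps_factor * np.median(finite))
        labels = cluster_optics_dbscan(
            reachability=opt.reachability_,
            core_distances=opt.core_distances_,
            ordering=opt.ordering_,
            eps=eps,
        )
    else:
        raise ValueError(f"unknown extraction method {method!r}")
    return ClusterSolution(
        algorithm="optics",
        labels=np.asarray(labels),
        ordering=opt.ordering_.copy(),
        reachability=opt.reachability_.copy(),
        min_samples=min_samples,
    )


def select_solution(sweep: ClusterSolution) -> dict:
    """Choose k from a k-means sweep by majority over three criteria.

    Criteria: (1) largest relative decrease in within-SS when moving to k;
    (2) maximum mean silhouette width; (3) maximum Dunn index. The
    combined choice is the majority vote, ties broken toward smaller k;
    disagreement between criteria is reported, never hidden.
    """
    if sweep.algorithm != "kmeans" or not sweep.within_ss:
        raise ValueError("select_solution expects a completed k-means sweep")
    ks = sorted(sweep.within_ss)
    rel_drop = {
        k: (sweep.within_ss[prev] - sweep.within_ss[k]) / sweep.within_ss[prev]
        for prev, k in zip(ks, ks[1:])
        if sweep.within_ss[prev] > 0
    }
    choice = {}
    if rel_drop:
        choice["elbow"] = max(sorted(rel_drop), key=lambda k: rel_drop[k])
    if sweep.silhouette:
        choice["silhouette"] = max(sorted(sweep.silhouette), key=lambda k: sweep.silhouette[k])
    if sweep.dunn:
        choice["dunn"] = max(sorted(sweep.dunn), key=lambda k: sweep.dunn[k])
    votes = pd.Series(list(choice.values())).value_counts()
    top = votes[votes == votes.max()].index.min()
    return {
        "k": int(top),
        "by_criterion": choice,
        "unanimous": len(set(choice.values())) == 1,
        "labels": sweep.labels_by_k.get(int(top)),
        "relative_ss_drop": rel_drop,
    }
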