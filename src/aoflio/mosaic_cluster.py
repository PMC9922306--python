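"""GMM clustering of cone phasor coordinates.

Cone phasors from one image aggregate into two groups: a smaller cluster
nearer the origin (longer effective lifetimes; putative S cones) and a larger
one to its right (M/L cones).  A Gaussian mixture model with axis-aligned
(diagonal) covariances, seeded by k-means, splits the coordinates; the smaller
final cluster is "Cluster 1" and its members are the putative S cones.  A
k=3 fit is available for multimodal phasor plots; after it, the two non-S
components (the two whose means have larger g) are merged into one cluster.

Rod regions are never clustered with cones; their phasors form a separate
third cluster summarized on its own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from . import stats_tests

__all__ = ["ClusterResult", "NoCallError", "fit_cone_gmm", "call_s_cones",
           "separation_test"]


class NoCallError(RuntimeError):
    """Raised when S-cone calls are requested from a non-converged clustering."""


@dataclass
class ClusterResult:
    """Outcome of clustering cone phasors into two final clusters.

    ``assignments`` maps each input point to final cluster id 1 (smaller,
    putative S) or 2 (larger).  ``k_used`` is the pre-merge component count.
    A degenerate or non-converging fit yields a single-cluster result with
    ``converged=False`` and all assignments equal to 2.
    """

    assignments: np.ndarray
    cluster_means: dict[int, tuple[float, float]]
    cluster_covs: dict[int, np.ndarray]
    s_cluster_id: int
    pct_cluster1: float
    k_used: int
    converged: bool
    seed: int

    @property
    def n_points(self) -> int:
        return len(self.assignments)


def _single_cluster_result(points: np.ndarray, k: int, seed: int) -> ClusterResult:
    mean = tuple(points.mean(axis=0)) if len(points) else (np.nan, np.nan)
    return ClusterResult(
        assignments=np.full(len(points), 2, dtype=int),
        cluster_means={2: mean},
        cluster_covs={2: np.var(points, axis=0) if len(points) else np.zeros(2)},
        s_cluster_id=1,
        pct_cluster1=0.0,
        k_used=k,
        converged=False,
        seed=seed,
    )


def _finalize(points: np.ndarray, raw_labels: np.ndarray, gmm: GaussianMixture,
              keep_component: int | None, k: int, seed: int) -> ClusterResult:
    """Merge non-S components (k=3), relabel by size, tie-break by mean g."""
    if keep_component is not None:
        s_raw = raw_labels == keep_component
    else:
        # k = 2: identify by size below
        s_raw = raw_labels == 0
    groups = {True: s_raw, False: ~s_raw}
    n_a, n_b = int(s_raw.sum()), int((~s_raw).sum())
    if keep_component is None:
        # choose smaller group; ties broken by smaller mean g
        if n_a < n_b:
            small = s_raw
        elif n_b < n_a:
            small = ~s_raw
        else:
            ga = points[s_raw, 0].mean() if n_a else np.inf
            gb = points[~s_raw, 0].mean() if n_b else np.inf
            small = s_raw if ga <= gb else ~s_raw
    else:
        small = s_raw
    assignments = np.where(small, 1, 2)
    means, covs = {}, {}
    for cid in (1, 2):
        sel = assignments == cid
        if sel.any():
            means[cid] = (float(points[sel, 0].mean()),
                          float(points[sel, 1].mean()))
            covs[cid] = np.diag(np.var(points[sel], axis=0, ddof=0))
    pct = 100.0 * float((assignments == 1).sum()) / len(points)
    return ClusterResult(
        assignments=assignments,
        cluster_means=means,
        cluster_covs=covs,
        s_cluster_id=1,
        pct_cluster1=pct,
        k_used=k,
        converged=True,
        seed=seed,
    )


def _try_gmm(points: np.ndarray, k: int, seed: int) -> ClusterResult | None:
    import warnings as _w

    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    with _w.catch_warnings():
        _w.simplefilter("ignore", ConvergenceWarning)
        km_labels = km.fit_predict(points)
    means = km.cluster_centers_
    variances = np.empty((k, 2))
    weights = np.empty(k)
    for j in range(k):
        sel = km_labels == j
        weights[j] = max(sel.mean(), 1e-6)
        v = np.var(points[sel], axis=0) if sel.sum() > 1 else np.zeros(2)
        variances[j] = np.maximum(v, 1e-12)
    weights /= weights.sum()
    gmm = GaussianMixture(
        n_components=k,
        covariance_type="diag",
        tol=1e-6,
        max_iter=500,
        weights_init=weights,
        means_init=means,
        precisions_init=1.0 / variances,
        random_state=seed,
    )
    try:
        with _w.catch_warnings():
            _w.simplefilter("ignore", ConvergenceWarning)
            labels = gmm.fit_predict(points)
    except Exception:
        return None
    if not gmm.converged_:
        return None
    if len(np.unique(labels)) < k:
        return None
    if k == 2:
        # relabel so component 0 is the smaller cluster (ties: smaller mean g)
        n0 = int((labels == 0).sum())
        n1 = int((labels == 1).sum())
        if n1 < n0 or (n1 == n0 and points[labels == 1, 0].mean()
                       < points[labels == 0, 0].mean()):
            labels = 1 - labels
        return _finalize(points, labels, gmm, None, k, seed)
    # k = 3: keep the component whose mean g is smallest as the S candidate
    keep = int(np.argmin(gmm.means_[:, 0]))
    return _finalize(points, labels, gmm, keep, k, seed)


def fit_cone_gmm(points: np.ndarray | list, k: int = 2,
                 seed: int = 0) -> ClusterResult:
    """Cluster cone phasor coordinates with a k-means-seeded diagonal GMM.

    ``k`` is 2 or 3; with k=3 the two components farther from the origin are
    merged afterwards so exactly two cone clusters remain.  A failed k=2 fit
    is retried at k=3; if both fail (or the points are degenerate), a
    single-cluster result with ``converged=False`` is returned.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (g, s)")
    if len(points) < 10:
        raise ValueError("need at least 10 points to cluster")
    if not np.all(np.isfinite(points)):
        raise ValueError("non-finite phasor coordinates")
    if k not in (2, 3):
        raise ValueError("k must be 2 or 3")
    if np.allclose(points.var(axis=0), 0.0):
        return _single_cluster_result(points, k, seed)
    result = _try_gmm(points, k, seed)
    if result is None and k == 2:
        result = _try_gmm(points, 3, seed)
    if result is None:
        return _single_cluster_result(points, k, seed)
    return result


def call_s_cones(result: ClusterResult) -> np.ndarray:
    """Boolean putative-S-cone call per cone (True = smaller cluster)."""
    if not result.converged:
        raise NoCallError("clustering did not converge; no S-cone call")
    return result.assignments == result.s_cluster_id


def separation_test(cluster_a: np.ndarray, cluster_b: np.ndarray,
                    paired: bool = False):
    """Hotelling's T-squared comparison of two phasor clusters' mean (g, s)."""
    a = np.asarray(cluster_a, dtype=float)
    b = np.asarray(cluster_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each cluster needs at least 3 points")
    if paired:
        return stats_tests.hotelling_paired(a, b)
    return stats_tests.hotelling_two_sample(a, b)
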