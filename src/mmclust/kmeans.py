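"""Hartigan-Wong k-means and the multi-start, multi-run stability protocol.

The core iteration moves single points between clusters using size-adjusted
transfer gains: moving point x from its cluster s (size n_s) to cluster t
(size n_t) decreases the within-cluster sum of squares (WCSS) exactly when

    n_t * d²(x, c_t) / (n_t + 1)  <  n_s * d²(x, c_s) / (n_s - 1),

with centroids updated live after every transfer.  This reaches lower WCSS
than Lloyd iterations because it accounts for the centroid shift a transfer
causes.

The stability protocol on top mirrors a two-level scheme: one *run* draws 25
random initial centroid sets (k distinct observations each) and keeps the
lowest-WCSS solution; 200 runs are executed and the minimum WCSS recorded.
If that minimum recurs in more than 10 runs the corresponding clustering is
accepted, otherwise 100 further runs are executed and the overall best kept.
Both levels are configurable so that desk-scale problems stay cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from sklearn.base import BaseEstimator, ClusterMixin

from .errors import InitializationError
from .preprocessing import WeightedDesign


@dataclass
class ClusteringResult:
    """One converged k-means solution in the weighted design space."""

    k: int
    assignments: np.ndarray  # n labels in [0, k)
    centroids: np.ndarray    # k x p, within-cluster means
    wcss: float
    converged: bool
    n_iter: int

    def validate(self, X: np.ndarray, rtol: float = 1e-8) -> "ClusteringResult":
        counts = np.bincount(self.assignments, minlength=self.k)
        if (counts == 0).any():
            raise ValueError("every cluster index must appear at least once")
        means = np.vstack(
            [X[self.assignments == g].mean(axis=0) for g in range(self.k)]
        )
        if not np.allclose(means, self.centroids, rtol=rtol, atol=1e-8):
            raise ValueError("centroids are not within-cluster means")
        wcss = float(((X - self.centroids[self.assignments]) ** 2).sum())
        if abs(wcss - self.wcss) > rtol * max(1.0, abs(wcss)):
            raise ValueError("stored WCSS inconsistent with assignments")
        return self


@dataclass
class ProtocolReport:
    """Outcome of the repeated-minimum-WCSS stability protocol."""

    best: ClusteringResult
    run_wcss: list[float]
    n_runs_total: int
    min_count: int
    extended: bool
    seed: int | None = None
    params: dict = field(default_factory=dict)


def _as_matrix(design) -> np.ndarray:
    if isinstance(design, WeightedDesign):
        X = design.matrix
    else:
        X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return np.ascontiguousarray(X, dtype=np.float64)


@njit(cache=True)
def _sqdist(x, c):
    s = 0.0
    for j in range(x.shape[0]):
        d = x[j] - c[j]
        s += d * d
    return s


@njit(cache=True)
def _hw_core(X, centers_in, max_iter):
    n, p = X.shape
    k = centers_in.shape[0]
    centers = centers_in.copy()
    labels = np.empty(n, np.int64)
    counts = np.zeros(k, np.int64)
    # Voronoi assignment to the initial centroids; ties to the lower index
    for i in range(n):
        best = 0
        bestd = _sqdist(X[i], centers[0])
        for t in range(1, k):
            d = _sqdist(X[i], centers[t])
            if d < bestd:
                bestd = d
                best = t
        labels[i] = best
        counts[best] += 1
    sums = np.zeros((k, p))
    for i in range(n):
        g = labels[i]
        for j in range(p):
            sums[g, j] += X[i, j]
    for g in range(k):
        if counts[g] > 0:
            for j in range(p):
                centers[g, j] = sums[g, j] / counts[g]
    # repair empty clusters: seed each with the point farthest from its centroid
    for g in range(k):
        if counts[g] == 0:
            far_i = -1
            far_d = -1.0
            for i in range(n):
                if counts[labels[i]] > 1:
                    d = _sqdist(X[i], centers[labels[i]])
                    if d > far_d:
                        far_d = d
                        far_i = i
            old = labels[far_i]
            counts[old] -= 1
            counts[g] = 1
            labels[far_i] = g
            for j in range(p):
                sums[old, j] -= X[far_i, j]
                centers[old, j] = sums[old, j] / counts[old]
                sums[g, j] = X[far_i, j]
                centers[g, j] = X[far_i, j]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        moved = 0
        for i in range(n):
            s = labels[i]
            if counts[s] <= 1:
                continue
            ds = _sqdist(X[i], centers[s])
            removal_gain = counts[s] * ds / (counts[s] - 1)
            best_t = -1
            best_cost = removal_gain
            for t in range(k):
                if t == s:
                    continue
                dt = _sqdist(X[i], centers[t])
                cost = counts[t] * dt / (counts[t] + 1)
                if cost < best_cost:
                    best_cost = cost
                    best_t = t
            if best_t >= 0:
                ns = counts[s]
                nt = counts[best_t]
                for j in range(p):
                    sums[s, j] -= X[i, j]
                    centers[s, j] = sums[s, j] / (ns - 1)
                    sums[best_t, j] += X[i, j]
                    centers[best_t, j] = sums[best_t, j] / (nt + 1)
                counts[s] = ns - 1
                counts[best_t] = nt + 1
                labels[i] = best_t
                moved += 1
        if moved == 0:
            converged = True
            break
    return labels, it, converged


def _finalize(X: np.ndarray, k: int, labels: np.ndarray, n_iter: int,
              converged: bool) -> ClusteringResult:
    # recompute exact centroids and WCSS to wash out incremental rounding
    centroids = np.zeros((k, X.shape[1]))
    for g in range(k):
        centroids[g] = X[labels == g].mean(axis=0)
    wcss = float(((X - centroids[labels]) ** 2).sum())
    return ClusteringResult(
        k=k,
        assignments=labels,
        centroids=centroids,
        wcss=wcss,
        converged=converged,
        n_iter=n_iter,
    )


def hartigan_wong(design, k: int, initial_centroids, max_iter: int = 100) -> ClusteringResult:
    """Run Hartigan-Wong k-means from explicit initial centroids."""
    X = _as_matrix(design)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must lie in [1, n={n}]")
    C = np.ascontiguousarray(np.atleast_2d(np.asarray(initial_centroids, dtype=float)))
    if C.shape != (k, X.shape[1]):
        raise InitializationError(
            f"initial centroids must be {k} x {X.shape[1]}, got {C.shape}"
        )
    if len(np.unique(C, axis=0)) < k:
        raise InitializationError("initial centroids must be k distinct points")
    labels, n_iter, converged = _hw_core(X, C, max_iter)
    return _finalize(X, k, labels, n_iter, converged)


def _sample_initial(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    for _ in range(100):
        idx = rng.choice(n, size=k, replace=False)
        C = X[idx]
        if len(np.unique(C, axis=0)) == k:
            return C
    if len(np.unique(X, axis=0)) < k:
        raise InitializationError(f"fewer than k={k} distinct observations")
    raise InitializationError("failed to sample k distinct initial centroids")


def best_of_starts(design, k: int, n_starts: int = 25,
                   rng: np.random.Generator | None = None,
                   max_iter: int = 100) -> ClusteringResult:
    """Best (lowest-WCSS) of ``n_starts`` random-observation initializations."""
    X = _as_matrix(design)
    rng = np.random.default_rng(rng)
    best: ClusteringResult | None = None
    for _ in range(n_starts):
        C = _sample_initial(X, k, rng)
        res = hartigan_wong(X, k, C, max_iter=max_iter)
        if best is None or res.wcss < best.wcss:
            best = res
    return best


def _run_rng(seed, run_index: int) -> np.random.Generator:
    # counter-derived substream: reproducible and independent of run order
    return np.random.default_rng(np.random.SeedSequence((seed, run_index)))


def stability_protocol(design, k: int, n_runs: int = 200,
                       recurrence_threshold: int = 10, extension_runs: int = 100,
                       n_starts: int = 25, seed: int = 0,
                       max_iter: int = 100) -> ProtocolReport:
    """Repeated minimum-WCSS protocol with recurrence check and extension.

    Executes ``n_runs`` best-of-``n_starts`` runs.  If the minimum WCSS recurs
    (within relative tolerance 1e-10) in more than ``recurrence_threshold``
    runs, the minimizing clustering is accepted; otherwise ``extension_runs``
    further runs are executed and the overall best returned.
    """
    X = _as_matrix(design)

    def do_runs(start: int, count: int):
        out = []
        for r in range(start, start + count):
            out.append(best_of_starts(X, k, n_starts=n_starts,
                                      rng=_run_rng(seed, r), max_iter=max_iter))
        return out

    results = do_runs(0, n_runs)
    run_wcss = [r.wcss for r in results]
    wmin = min(run_wcss)
    min_count = sum(1 for w in run_wcss if w <= wmin * (1 + 1e-10) + 1e-300)
    extended = False
    if min_count <= recurrence_threshold and extension_runs > 0:
        extended = True
        results += do_runs(n_runs, extension_runs)
        run_wcss = [r.wcss for r in results]
        wmin = min(run_wcss)
        min_count = sum(1 for w in run_wcss if w <= wmin * (1 + 1e-10) + 1e-300)
    best = results[int(np.argmin(run_wcss))]
    return ProtocolReport(
        best=best,
        run_wcss=run_wcss,
        n_runs_total=len(results),
        min_count=min_count,
        extended=extended,
        seed=seed,
        params={
            "n_runs": n_runs,
            "recurrence_threshold": recurrence_threshold,
            "extension_runs": extension_runs,
            "n_starts": n_starts,
            "max_iter": max_iter,
        },
    )


class WeightedKMeans(BaseEstimator, ClusterMixin):
    """Hartigan-Wong k-means with the repeated-minimum-WCSS stability protocol.

    Scikit-learn style clusterer.  ``fit`` expects data already mapped into
    the weighted clustering space (e.g. by :class:`DomainBalancedScaler` in a
    Pipeline) and runs the full protocol: ``n_runs`` runs of the best of
    ``n_starts`` random initializations, a recurrence check on the minimum
    WCSS, and an optional block of ``extension_runs`` further runs.

    Parameters default to the full-scale protocol (200 runs of 25 starts,
    recurrence threshold 10, extension 100); desk-scale work should lower
    ``n_runs``/``n_starts``.

    Attributes
    ----------
    labels_ : ndarray of shape (n,)
        0-based cluster assignments of the best solution.
    cluster_centers_ : ndarray of shape (k, p)
        Within-cluster means in the weighted space.
    inertia_ : float
        WCSS of the best solution.
    protocol_report_ : ProtocolReport
        Full run-level record (per-run minima, recurrence count, extension).
    """

    def __init__(self, n_clusters: int = 4, n_runs: int = 200, n_starts: int = 25,
                 recurrence_threshold: int = 10, extension_runs: int = 100,
                 max_iter: int = 100, random_state: int | None = None):
        self.n_clusters = n_clusters
        self.n_runs = n_runs
        self.n_starts = n_starts
        self.recurrence_threshold = recurrence_threshold
        self.extension_runs = extension_runs
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        seed = 0 if self.random_state is None else int(self.random_state)
        report = stability_protocol(
            X, self.n_clusters, n_runs=self.n_runs,
            recurrence_threshold=self.recurrence_threshold,
            extension_runs=self.extension_runs, n_starts=self.n_starts,
            seed=seed, max_iter=self.max_iter,
        )
        self.protocol_report_ = report
        self.labels_ = report.best.assignments
        self.cluster_centers_ = report.best.centroids
        self.inertia_ = report.best.wcss
        self.n_iter_ = report.best.n_iter
        self.n_features_in_ = _as_matrix(X).shape[1]
        return self

    def predict(self, X):
        X = _as_matrix(X)
        d = ((X[:, None, :] - self.cluster_centers_[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d, axis=1)  # argmin ties resolve to the lower index
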