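"""Cluster-number selection curves: WCSS elbow, Calinski-Harabasz, simplified silhouette.

All three criteria are computed in the weighted design space — the same space
the WCSS is minimized in — so they are directly comparable across k.  The
package reports the curves and the per-index argmax but deliberately does not
auto-pick k: the final choice combines statistical criteria with model
simplicity and clinical interpretability, which is a judgment call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kmeans import ClusteringResult, ProtocolReport, _as_matrix, stability_protocol


def calinski_harabasz(design, result: ClusteringResult) -> float:
    """Variance-ratio index (BCSS/(k-1)) / (WCSS/(n-k)); higher is better.

    Returns +inf when WCSS is exactly zero (all points coincide with their
    centroids).
    """
    X = _as_matrix(design)
    n = X.shape[0]
    k = result.k
    if k <= 1 or k >= n:
        raise ValueError(f"Calinski-Harabasz requires 1 < k < n, got k={k}, n={n}")
    grand = X.mean(axis=0)
    counts = np.bincount(result.assignments, minlength=k)
    bcss = float((counts[:, None] * (result.centroids - grand) ** 2).sum())
    wcss = float(((X - result.centroids[result.assignments]) ** 2).sum())
    if wcss == 0.0:
        return float("inf")
    return (bcss / (k - 1)) / (wcss / (n - k))


def simplified_silhouette(design, result: ClusteringResult) -> float:
    """Mean centroid-based silhouette: s_i = (b_i - a_i) / max(a_i, b_i).

    a_i is the distance to the point's own centroid, b_i the minimum distance
    to any other centroid; s_i is defined as 0 when a_i = b_i = 0.  The
    centroid-based variant is what keeps the score tractable at registry
    scale (O(nk) instead of O(n²)).
    """
    X = _as_matrix(design)
    if result.k < 2:
        raise ValueError("silhouette requires k >= 2")
    d = np.sqrt(((X[:, None, :] - result.centroids[None, :, :]) ** 2).sum(axis=2))
    a = d[np.arange(X.shape[0]), result.assignments]
    d_other = d.copy()
    d_other[np.arange(X.shape[0]), result.assignments] = np.inf
    b = d_other.min(axis=1)
    denom = np.maximum(a, b)
    s = np.zeros_like(a)
    nz = denom > 0
    s[nz] = (b[nz] - a[nz]) / denom[nz]
    return float(s.mean())


@dataclass
class SelectionCurve:
    """Per-k selection criteria over a k range."""

    ks: list[int]
    wcss: list[float]
    ch_index: list[float]
    silhouette: list[float]
    reports: list[ProtocolReport]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": self.ks, "wcss": self.wcss, "calinski_harabasz": self.ch_index,
             "simplified_silhouette": self.silhouette}
        )

    def suggest(self) -> dict[str, int]:
        """Per-index argmax (convenience only; k choice remains the user's)."""
        return {
            "calinski_harabasz": self.ks[int(np.argmax(self.ch_index))],
            "simplified_silhouette": self.ks[int(np.argmax(self.silhouette))],
        }


def selection_curve(design, k_min: int = 2, k_max: int = 20,
                    n_runs: int = 200, recurrence_threshold: int = 10,
                    extension_runs: int = 100, n_starts: int = 25,
                    seed: int = 0, max_iter: int = 100) -> SelectionCurve:
    """Run the stability protocol for each k in [k_min, k_max] and score it."""
    X = _as_matrix(design)
    n = X.shape[0]
    if not 2 <= k_min <= k_max < n:
        raise ValueError(f"need 2 <= k_min <= k_max < n, got [{k_min}, {k_max}], n={n}")
    ks, wcss, ch, sil, reports = [], [], [], [], []
    for k in range(k_min, k_max + 1):
        report = stability_protocol(
            X, k, n_runs=n_runs, recurrence_threshold=recurrence_threshold,
            extension_runs=extension_runs, n_starts=n_starts,
            seed=seed + k, max_iter=max_iter,
        )
        ks.append(k)
        wcss.append(report.best.wcss)
        ch.append(calinski_harabasz(X, report.best))
        sil.append(simplified_silhouette(X, report.best))
        reports.append(report)
    diffs = np.diff(wcss)
    if (diffs > 1e-8 * np.maximum(1.0, np.abs(wcss[:-1]))).any():
        warnings.warn(
            "WCSS increased with k on this curve; some k likely converged to a "
            "local optimum — consider more runs/starts",
            RuntimeWarning,
            stacklevel=2,
        )
    return SelectionCurve(ks, wcss, ch, sil, reports)


def plot_elbow(curve: SelectionCurve, path=None):
    """Three-panel selection plot (WCSS elbow, CH index, simplified silhouette)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    for ax, ys, label in zip(
        axes,
        (curve.wcss, curve.ch_index, curve.silhouette),
        ("WCSS", "Calinski-Harabasz", "Simplified silhouette"),
    ):
        ax.plot(curve.ks, ys, marker="o")
        ax.set_xlabel("k")
        ax.set_ylabel(label)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
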