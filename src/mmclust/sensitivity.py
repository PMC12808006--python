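"""Weight-perturbation robustness check.

The domain-balancing weight w = sqrt(p_c/p_u) equalizes the condition and
utilization blocks.  To test whether the clustering hinges on that exact
balance, the design is rebuilt with 0.5*w and 2*w (utilization counting half
or twice as much), the full stability protocol is rerun at the same k, the
perturbed clusters are matched to the base solution by maximum-overlap
optimal assignment (Hungarian algorithm on the contingency matrix), and a
confusion matrix plus the diagonal agreement fraction is reported per factor.
The goal is assessing robustness of the solution, not optimizing the weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .data_model import CohortMatrix
from .kmeans import ProtocolReport, stability_protocol
from .preprocessing import apply_weight, compute_domain_weight, standardize


def contingency_matrix(base, other, k: int) -> np.ndarray:
    """k x k overlap counts between two 0-based label vectors."""
    base = np.asarray(base)
    other = np.asarray(other)
    if base.shape != other.shape:
        raise ValueError("assignment vectors must have equal length")
    if base.min() < 0 or base.max() >= k or other.min() < 0 or other.max() >= k:
        raise ValueError(f"labels out of range [0, {k})")
    M = np.zeros((k, k), dtype=np.int64)
    np.add.at(M, (base, other), 1)
    return M


def match_clusters(base, other, k: int) -> np.ndarray:
    """Relabeling of ``other`` maximizing diagonal overlap with ``base``.

    Returns ``perm`` with ``perm[j] = i`` meaning other-cluster j is matched
    to base-cluster i; solutions with unequal k are handled upstream by
    padding the contingency matrix with empty clusters.
    """
    M = contingency_matrix(base, other, k)
    row_ind, col_ind = linear_sum_assignment(-M)
    perm = np.empty(k, dtype=np.int64)
    perm[col_ind] = row_ind
    return perm


def matched_confusion(base, other, k: int) -> tuple[np.ndarray, np.ndarray, float]:
    """(confusion matrix with matched columns, permutation, diagonal agreement)."""
    perm = match_clusters(base, other, k)
    relabeled = perm[np.asarray(other)]
    M = contingency_matrix(base, relabeled, k)
    agreement = float(np.trace(M)) / len(base)
    return M, perm, agreement


@dataclass
class SensitivityReport:
    """Per-factor matched confusion matrices and diagonal agreements."""

    k: int
    factors: list[float]
    confusions: dict[float, np.ndarray]
    agreements: dict[float, float]
    permutations: dict[float, np.ndarray]
    base_report: ProtocolReport | None = None
    perturbed_reports: dict[float, ProtocolReport] = field(default_factory=dict)

    def agreement_percent(self, factor: float, ndigits: int = 1) -> float:
        return round(100.0 * self.agreements[factor], ndigits)


def weight_sensitivity_blocks(
    conditions, utilization, k: int,
    factors: tuple[float, ...] = (0.5, 2.0),
    n_runs: int = 200, recurrence_threshold: int = 10, extension_runs: int = 100,
    n_starts: int = 25, seed: int = 0, max_iter: int = 100,
    base_assignments=None,
) -> SensitivityReport:
    """Core sensitivity analysis on raw (unstandardized) variable blocks.

    Standardizes both blocks once, clusters at weight f * sqrt(p_c/p_u) for
    f = 1 (base, unless ``base_assignments`` is given) and each factor, then
    matches each perturbed solution to the base.
    """
    conditions = np.asarray(conditions, dtype=float)
    utilization = np.asarray(utilization, dtype=float)
    if conditions.ndim == 1:
        conditions = conditions[:, None]
    if utilization.ndim == 1:
        utilization = utilization[:, None]
    p_c, p_u = conditions.shape[1], utilization.shape[1]
    Z, _, _ = standardize(np.hstack([conditions, utilization]))
    w = compute_domain_weight(p_c, p_u)

    def run(factor: float, substream: int) -> ProtocolReport:
        design = apply_weight(Z, factor * w, p_c, p_u)
        return stability_protocol(
            design, k, n_runs=n_runs, recurrence_threshold=recurrence_threshold,
            extension_runs=extension_runs, n_starts=n_starts,
            seed=int(np.random.SeedSequence((seed, substream)).generate_state(1)[0] % (2**31)),
            max_iter=max_iter,
        )

    base_report = None
    if base_assignments is None:
        base_report = run(1.0, 0)
        base_assignments = base_report.best.assignments
    base_assignments = np.asarray(base_assignments)

    confusions, agreements, perms, reports = {}, {}, {}, {}
    for i, f in enumerate(factors, start=1):
        rep = run(float(f), i)
        M, perm, agreement = matched_confusion(base_assignments, rep.best.assignments, k)
        confusions[f] = M
        agreements[f] = agreement
        perms[f] = perm
        reports[f] = rep
    return SensitivityReport(
        k=k, factors=list(factors), confusions=confusions, agreements=agreements,
        permutations=perms, base_report=base_report, perturbed_reports=reports,
    )


def weight_sensitivity(
    cohort: CohortMatrix, k: int, factors: tuple[float, ...] = (0.5, 2.0),
    base_assignments=None, **protocol_params,
) -> SensitivityReport:
    """Cohort-level wrapper around :func:`weight_sensitivity_blocks`."""
    return weight_sensitivity_blocks(
        cohort.conditions.to_numpy(), cohort.utilization.to_numpy(), k,
        factors=factors, base_assignments=base_assignments, **protocol_params,
    )
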