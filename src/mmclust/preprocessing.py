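"""Standardization and domain-balancing weight.

All clustering variables (33 binary condition indicators and 7 utilization
counts) are standardized to zero mean and unit variance.  Because the
condition block has more columns, it would dominate squared Euclidean
distances; the utilization block is therefore multiplied by

    w = sqrt(p_c / p_u) = sqrt(33 / 7)

after standardization.  Under independent standardized columns the expected
squared pairwise distance contributed by a block is proportional to its column
count, so this weight equalizes the two blocks' expected contributions.
WCSS and all validity indices downstream are computed in this weighted space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .data_model import CohortMatrix
from .errors import ZeroVarianceError


@dataclass
class WeightedDesign:
    """Standardized, domain-weighted numeric design matrix.

    Column layout: the ``p_c`` condition columns first, then the ``p_u``
    utilization columns (already multiplied by ``weight``).
    """

    matrix: np.ndarray
    col_means: np.ndarray
    col_sds: np.ndarray
    weight: float
    p_c: int
    p_u: int
    columns: tuple[str, ...] = ()

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def compute_domain_weight(p_c: int, p_u: int) -> float:
    """Balancing weight sqrt(p_c / p_u) for the utilization block."""
    if p_c < 1 or p_u < 1:
        raise ValueError("column counts must be positive integers")
    return float(np.sqrt(p_c / p_u))


def standardize(X) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise (x - mean) / sd with sample SD (ddof=1).

    Returns (Z, means, sds).  A zero-variance column (e.g. a condition nobody
    or everybody has) cannot be standardized and raises ZeroVarianceError.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    X = np.asarray(X, dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        label = names[zero[0]] if names else f"index {zero[0]}"
        raise ZeroVarianceError(f"zero-variance column: {label}")
    return (X - means) / sds, means, sds


def unstandardize(Z, col_means, col_sds) -> np.ndarray:
    """Inverse of :func:`standardize`."""
    return np.asarray(Z, dtype=float) * col_sds + col_means


def apply_weight(Z, weight: float, p_c: int, p_u: int) -> np.ndarray:
    """Multiply the trailing ``p_u`` (utilization) columns by ``weight``."""
    Z = np.asarray(Z, dtype=float)
    if Z.shape[1] != p_c + p_u:
        raise ValueError(f"expected {p_c + p_u} columns, got {Z.shape[1]}")
    out = Z.copy()
    out[:, p_c:] *= weight
    return out


def build_design(cohort: CohortMatrix, weight_factor: float = 1.0) -> WeightedDesign:
    """Cohort -> standardized, weighted design (conditions then utilization).

    ``weight_factor`` scales the balancing weight (sensitivity analyses use
    0.5 and 2.0); sociodemographics never enter the design.
    """
    frame = pd.concat([cohort.conditions, cohort.utilization], axis=1)
    p_c = cohort.catalog.n_conditions
    p_u = cohort.util_schema.n_variables
    Z, means, sds = standardize(frame)
    w = weight_factor * compute_domain_weight(p_c, p_u)
    return WeightedDesign(
        matrix=apply_weight(Z, w, p_c, p_u),
        col_means=means,
        col_sds=sds,
        weight=w,
        p_c=p_c,
        p_u=p_u,
        columns=tuple(frame.columns),
    )


class DomainBalancedScaler(BaseEstimator, TransformerMixin):
    """Standardize all columns, then reweight the trailing utilization block.

    Scikit-learn style transformer: the input is an ``n x (p_c + p_u)`` array
    whose last ``n_util_cols`` columns form the utilization block.  After
    ``fit``, ``transform`` maps data into the weighted clustering space and
    ``inverse_transform`` maps back.

    Parameters
    ----------
    n_util_cols : int
        Number of trailing utilization columns (default 7).
    weight_factor : float
        Scalar multiplier on the balancing weight sqrt(p_c/p_u); 1.0 is the
        balanced default, 0.5 and 2.0 are the sensitivity-analysis limits.
    """

    def __init__(self, n_util_cols: int = 7, weight_factor: float = 1.0):
        self.n_util_cols = n_util_cols
        self.weight_factor = weight_factor

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] <= self.n_util_cols:
            raise ValueError(
                "X must be 2-D with more columns than the utilization block"
            )
        _, self.col_means_, self.col_sds_ = standardize(X)
        self.p_u_ = self.n_util_cols
        self.p_c_ = X.shape[1] - self.p_u_
        self.weight_ = self.weight_factor * compute_domain_weight(self.p_c_, self.p_u_)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        Z = (np.asarray(X, dtype=float) - self.col_means_) / self.col_sds_
        return apply_weight(Z, self.weight_, self.p_c_, self.p_u_)

    def inverse_transform(self, X):
        Z = np.asarray(X, dtype=float).copy()
        Z[:, self.p_c_:] /= self.weight_
        return unstandardize(Z, self.col_means_, self.col_sds_)

    def to_sidecar(self) -> dict:
        """Scaling parameters as a JSON/YAML-serializable dict."""
        return {
            "col_means": self.col_means_.tolist(),
            "col_sds": self.col_sds_.tolist(),
            "weight": float(self.weight_),
            "p_c": int(self.p_c_),
            "p_u": int(self.p_u_),
        }
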