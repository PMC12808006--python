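"""Cluster characterization: prevalence and O/E tables, portfolios, descriptives.

Cluster profiles follow the reporting conventions of registry multimorbidity
studies:

* condition prevalence per cluster with observed/expected (O/E) ratios —
  cluster prevalence divided by the prevalence in the whole multimorbid
  population; O/E > 1 marks over-representation, and the percent increase is
  (O/E - 1) * 100.  O/E is always computed from unrounded prevalences; only
  the printed reproduction rounds (half-up, two decimals).
* chronic-condition portfolios — the *exact* set of conditions a person has:
  a portfolio of size m counts only people with exactly those m conditions
  and no others.  A secondary variant drops the three risk-factor conditions
  (hypertension, high cholesterol, obesity) before forming the set, so people
  may fall below two conditions and then contribute to no portfolio.
* sociodemographic percentage distributions with lowest/highest-cluster
  annotations, raw (unstandardized) utilization means, and the distribution
  of condition counts (2..9, >= 10).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .data_model import CohortMatrix, SOCIODEMO_VARIABLES
from .errors import AlignmentError


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up, the rule used for printed-table reproduction."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def observed_expected(cluster_prevalence: float, overall_prevalence: float) -> float:
    """O/E ratio; NaN sentinel when the overall prevalence is zero."""
    if overall_prevalence == 0:
        return float("nan")
    return cluster_prevalence / overall_prevalence


def percent_increase(oe: float) -> float:
    """Percent increase over expectation implied by an O/E ratio."""
    return (oe - 1.0) * 100.0


def _check_alignment(n: int, assignments) -> np.ndarray:
    a = np.asarray(assignments)
    if a.shape != (n,):
        raise AlignmentError(f"assignments have shape {a.shape}, expected ({n},)")
    return a


def _cluster_ids(assignments: np.ndarray) -> list:
    return sorted(pd.unique(assignments).tolist())


@dataclass
class PrevalenceTable:
    """Per-condition overall and per-cluster prevalence with O/E annotations."""

    overall: pd.Series                 # fraction per condition
    prevalence: pd.DataFrame           # condition x cluster, fractions
    oe: pd.DataFrame                   # condition x cluster
    pct_increase: pd.DataFrame         # condition x cluster
    over_expected: pd.DataFrame        # condition x cluster, O/E > 1

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"overall": self.overall})
        for g in self.prevalence.columns:
            out[f"prev_{g}"] = self.prevalence[g]
            out[f"oe_{g}"] = self.oe[g]
            out[f"pct_increase_{g}"] = self.pct_increase[g]
            out[f"over_expected_{g}"] = self.over_expected[g]
        return out


def prevalence_and_oe(cohort: CohortMatrix, assignments) -> PrevalenceTable:
    """Within-cluster condition prevalences, O/E ratios and percent increases."""
    a = _check_alignment(cohort.n, assignments)
    cond = cohort.conditions.astype(float)
    overall = cond.mean(axis=0)
    clusters = _cluster_ids(a)
    prev = pd.DataFrame(
        {g: cond[a == g].mean(axis=0) for g in clusters}, index=cond.columns
    )
    oe = prev.divide(overall.replace(0, np.nan), axis=0)
    return PrevalenceTable(
        overall=overall,
        prevalence=prev,
        oe=oe,
        pct_increase=(oe - 1.0) * 100.0,
        over_expected=oe > 1.0,
    )


def portfolios(
    cohort: CohortMatrix,
    assignments,
    sizes: tuple[int, ...] = (2, 3, 4),
    include_risk_factors: bool = True,
    top_n: int = 5,
) -> pd.DataFrame:
    """Rank exact condition combinations per cluster and portfolio size.

    Each person contributes to exactly one combination: the one equal to their
    full (optionally risk-factor-free) condition set.  Percentages use the
    cluster size as denominator.  Ties rank by count descending, then
    lexicographically by the sorted condition names.
    """
    a = _check_alignment(cohort.n, assignments)
    names = np.array(cohort.catalog.names)
    keep = np.ones(len(names), dtype=bool)
    if not include_risk_factors:
        keep = ~np.isin(names, cohort.catalog.risk_factor_names)
    cond = cohort.conditions.to_numpy().astype(bool)[:, keep]
    kept_names = names[keep]
    clusters = _cluster_ids(a)
    rows = []
    for g in clusters:
        members = np.flatnonzero(a == g)
        cluster_size = members.size
        counter: Counter = Counter()
        for i in members:
            combo = tuple(sorted(kept_names[cond[i]]))  # alphabetical, for stable ties
            if len(combo) in sizes:
                counter[combo] += 1
        for m in sizes:
            ranked = sorted(
                ((combo, cnt) for combo, cnt in counter.items() if len(combo) == m),
                key=lambda item: (-item[1], item[0]),
            )[:top_n]
            for rank, (combo, cnt) in enumerate(ranked, start=1):
                rows.append(
                    {
                        "cluster": g,
                        "size": m,
                        "rank": rank,
                        "conditions": " + ".join(combo),
                        "count": cnt,
                        "pct_of_cluster": 100.0 * cnt / cluster_size,
                        "risk_factors_included": include_risk_factors,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["cluster", "size", "rank", "conditions", "count",
                 "pct_of_cluster", "risk_factors_included"],
    )


def sociodemographic_profile(cohort: CohortMatrix, assignments) -> pd.DataFrame:
    """Percent distribution of each sociodemographic category per cluster.

    Returns a tidy frame with one row per (variable, category): per-cluster
    percentages, the overall percentage, and the lowest/highest cluster for
    that category (ties resolve to the lower cluster label).
    """
    a = _check_alignment(cohort.n, assignments)
    clusters = _cluster_ids(a)
    rows = []
    for var in SOCIODEMO_VARIABLES:
        col = cohort.sociodemo[var]
        cats = list(pd.unique(col))
        for cat in cats:
            row = {"variable": var, "category": cat}
            pcts = {}
            for g in clusters:
                sel = col[a == g]
                pcts[g] = 100.0 * (sel == cat).mean() if len(sel) else 0.0
                row[f"pct_{g}"] = pcts[g]
            row["pct_all"] = 100.0 * (col == cat).mean()
            lo, hi = min(pcts.values()), max(pcts.values())
            row["lowest"] = next(g for g in clusters if pcts[g] == lo)
            row["highest"] = next(g for g in clusters if pcts[g] == hi)
            rows.append(row)
    out = pd.DataFrame(rows)
    if "age" in cohort.sociodemo.columns:  # optional numeric age column
        age = pd.to_numeric(cohort.sociodemo["age"])
        row = {"variable": "age", "category": "mean"}
        for g in clusters:
            row[f"pct_{g}"] = float(age[a == g].mean())
        row["pct_all"] = float(age.mean())
        out = pd.concat([out, pd.DataFrame([row])], ignore_index=True)
    return out


def utilization_and_counts(
    cohort: CohortMatrix, assignments
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Raw utilization means, condition-count distribution, mean condition count.

    Returns ``(util_means, count_distribution, mean_conditions)``: utilization
    means are arithmetic means of the unstandardized counts per cluster (plus
    an ``all`` column); the condition-count distribution is the percentage of
    people with 2..9 and >= 10 conditions.
    """
    a = _check_alignment(cohort.n, assignments)
    clusters = _cluster_ids(a)
    util = cohort.utilization.astype(float)
    util_means = pd.DataFrame({g: util[a == g].mean(axis=0) for g in clusters})
    util_means["all"] = util.mean(axis=0)

    counts = cohort.condition_counts()
    bins = [str(c) for c in range(2, 10)] + [">=10"]

    def dist(mask) -> pd.Series:
        c = counts[mask]
        vals = [100.0 * ((c == v).sum() / c.size) for v in range(2, 10)]
        vals.append(100.0 * ((c >= 10).sum() / c.size))
        return pd.Series(vals, index=bins)

    count_dist = pd.DataFrame({g: dist(a == g) for g in clusters})
    count_dist["all"] = dist(np.ones(cohort.n, dtype=bool))
    mean_conditions = pd.Series(
        {g: float(counts[a == g].mean()) for g in clusters} | {"all": float(counts.mean())}
    )
    return util_means, count_dist, mean_conditions


@dataclass
class ClusterProfiles:
    """Full descriptive profile of a clustering solution."""

    cluster_sizes: pd.Series
    cluster_pct: pd.Series
    prevalence: PrevalenceTable
    portfolios_with_rf: pd.DataFrame
    portfolios_without_rf: pd.DataFrame
    sociodemo: pd.DataFrame
    utilization_means: pd.DataFrame
    condition_count_dist: pd.DataFrame
    mean_conditions: pd.Series

    def summary(self) -> str:
        lines = ["Cluster sizes:"]
        for g, size in self.cluster_sizes.items():
            lines.append(f"  cluster {g}: {size} ({round_half_up(self.cluster_pct[g])}%)")
        lines.append("Mean conditions per cluster:")
        for g, v in self.mean_conditions.items():
            lines.append(f"  {g}: {round_half_up(v)}")
        return "\n".join(lines)


def cluster_profiles(cohort: CohortMatrix, assignments, top_n: int = 5) -> ClusterProfiles:
    """Compute every descriptive table for one clustering solution."""
    a = _check_alignment(cohort.n, assignments)
    clusters = _cluster_ids(a)
    sizes = pd.Series({g: int((a == g).sum()) for g in clusters})
    util_means, count_dist, mean_cond = utilization_and_counts(cohort, a)
    return ClusterProfiles(
        cluster_sizes=sizes,
        cluster_pct=100.0 * sizes / cohort.n,
        prevalence=prevalence_and_oe(cohort, a),
        portfolios_with_rf=portfolios(cohort, a, include_risk_factors=True, top_n=top_n),
        portfolios_without_rf=portfolios(cohort, a, include_risk_factors=False, top_n=top_n),
        sociodemo=sociodemographic_profile(cohort, a),
        utilization_means=util_means,
        condition_count_dist=count_dist,
        mean_conditions=mean_cond,
    )
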