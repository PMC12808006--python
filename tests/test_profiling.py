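from collections import Counter

import numpy as np
import pandas as pd
import pytest

import mmclust as mm
from mmclust.data_model import CohortMatrix, SOCIODEMO_VARIABLES
from mmclust.errors import AlignmentError
from mmclust.profiling import percent_increase, round_half_up


def make_cohort(condition_sets, sociodemo=None, utilization=None):
    """Build a cohort from explicit per-person condition-name sets."""
    cat = mm.ConditionCatalog.default()
    util = mm.UtilizationSchema()
    n = len(condition_sets)
    cond = pd.DataFrame(0, index=range(n), columns=list(cat.names))
    for i, names in enumerate(condition_sets):
        cond.loc[i, list(names)] = 1
    u = pd.DataFrame(
        utilization if utilization is not None else np.zeros((n, 7), dtype=np.int64),
        columns=list(util.names),
    )
    s = pd.DataFrame(
        sociodemo if sociodemo is not None
        else {v: ["unknown"] * n for v in SOCIODEMO_VARIABLES}
    )
    return CohortMatrix(
        person_id=pd.Series([f"p{i}" for i in range(n)], name="person_id"),
        conditions=cond, utilization=u, sociodemo=s,
        catalog=cat, util_schema=util,
    )


class TestObservedExpected:
    def test_published_ratio_worked_examples(self):
        # depression: cluster prevalence 53.69% vs overall 20.55% -> O/E 2.61
        assert round_half_up(mm.observed_expected(53.69, 20.55)) == 2.61
        # O/E 7.41 corresponds to a 641% increase
        assert round_half_up(percent_increase(7.41), 0) == 641.0

    def test_oe_identity_when_cluster_matches_overall(self):
        assert mm.observed_expected(10.0, 10.0) == 1.0
        assert percent_increase(1.0) == 0.0

    def test_zero_overall_prevalence_gives_nan_sentinel(self):
        assert np.isnan(mm.observed_expected(0.0, 0.0))


class TestPrevalenceTable:
    @pytest.fixture()
    def cohort_and_labels(self):
        sets = (
            [{"depression", "anxiety"}] * 6
            + [{"hypertension", "depression"}] * 2
            + [{"hypertension", "osteoarthritis"}] * 8
        )
        return make_cohort(sets), np.array([0] * 8 + [1] * 8)

    def test_prevalences_and_oe(self, cohort_and_labels):
        cohort, labels = cohort_and_labels
        table = mm.prevalence_and_oe(cohort, labels)
        # depression: cluster0 8/8, cluster1 0/8, overall 8/16
        assert table.overall["depression"] == 0.5
        assert table.prevalence.loc["depression", 0] == 1.0
        assert table.oe.loc["depression", 0] == pytest.approx(2.0)
        assert table.pct_increase.loc["depression", 0] == pytest.approx(100.0)
        assert bool(table.over_expected.loc["depression", 0])
        assert not bool(table.over_expected.loc["depression", 1])
        # a condition nobody has carries the NaN sentinel
        assert np.isnan(table.oe.loc["stroke", 0])

    def test_pooled_prevalence_is_size_weighted_cluster_average(self, cohort_and_labels):
        cohort, labels = cohort_and_labels
        table = mm.prevalence_and_oe(cohort, labels)
        sizes = np.array([(labels == g).sum() for g in table.prevalence.columns])
        pooled = (table.prevalence * sizes).sum(axis=1) / sizes.sum()
        pd.testing.assert_series_equal(pooled, table.overall, check_names=False)

    def test_misaligned_assignments_rejected(self, cohort_and_labels):
        cohort, labels = cohort_and_labels
        with pytest.raises(AlignmentError):
            mm.prevalence_and_oe(cohort, labels[:-1])


class TestPortfolios:
    def test_exact_set_semantics(self):
        cohort = make_cohort(
            [{"depression", "anxiety"},
             {"depression", "anxiety"},
             {"depression", "anxiety", "epilepsy"}]
        )
        labels = np.zeros(3, dtype=int)
        table = mm.portfolios(cohort, labels, top_n=5)
        two = table[table["size"] == 2]
        assert len(two) == 1
        assert two.iloc[0]["conditions"] == "anxiety + depression"
        assert two.iloc[0]["count"] == 2  # the 3-condition person does NOT count
        three = table[table["size"] == 3]
        assert three.iloc[0]["count"] == 1
        assert two.iloc[0]["pct_of_cluster"] == pytest.approx(100 * 2 / 3)

    def test_risk_factor_exclusion_recomputes_cardinality(self):
        cohort = make_cohort(
            [{"hypertension", "depression"},       # -> {depression}: size 1, dropped
             {"hypertension", "depression", "anxiety"},  # -> size-2 set
             {"depression", "anxiety"}]
        )
        labels = np.zeros(3, dtype=int)
        table = mm.portfolios(cohort, labels, include_risk_factors=False)
        assert (table["size"] == 2).all()
        assert table.iloc[0]["count"] == 2  # both residual {anxiety, depression}
        assert table["count"].sum() == 2

    def test_rank_matches_brute_force_count(self):
        rng = np.random.default_rng(0)
        cat = mm.ConditionCatalog.default()
        sets = []
        for _ in range(40):
            m = int(rng.integers(2, 5))
            sets.append(set(rng.choice(cat.names, size=m, replace=False)))
        sets += [{"copd", "allergies"}] * 10  # planted dominant pair
        cohort = make_cohort(sets)
        labels = np.zeros(len(sets), dtype=int)
        table = mm.portfolios(cohort, labels, top_n=3)
        top2 = table[(table["size"] == 2) & (table["rank"] == 1)].iloc[0]
        brute = Counter(frozenset(s) for s in sets if len(s) == 2)
        combo, count = max(brute.items(), key=lambda kv: kv[1])
        assert top2["count"] == count
        assert set(top2["conditions"].split(" + ")) == set(combo)

    def test_counts_partition_persons_by_cardinality(self):
        rng = np.random.default_rng(3)
        cat = mm.ConditionCatalog.default()
        sets = [
            set(rng.choice(cat.names, size=int(rng.integers(2, 6)), replace=False))
            for _ in range(60)
        ]
        cohort = make_cohort(sets)
        labels = np.zeros(60, dtype=int)
        table = mm.portfolios(cohort, labels, sizes=(2, 3, 4, 5), top_n=10**9)
        for m in (2, 3, 4, 5):
            n_m = sum(1 for s in sets if len(s) == m)
            assert table[table["size"] == m]["count"].sum() == n_m


class TestDescriptives:
    def test_sociodemo_percentages_sum_to_100_and_flags(self):
        socio = {v: ["x"] * 10 for v in SOCIODEMO_VARIABLES}
        socio["sex"] = ["female"] * 3 + ["male"] * 2 + ["female"] * 2 + ["male"] * 3
        cohort = make_cohort([{"copd", "allergies"}] * 10, sociodemo=socio)
        labels = np.array([0] * 5 + [1] * 5)
        prof = mm.sociodemographic_profile(cohort, labels)
        sex = prof[prof["variable"] == "sex"].set_index("category")
        assert sex.loc["female", "pct_0"] == 60.0
        assert sex.loc["female", "pct_1"] == 40.0
        assert sex.loc["female", "highest"] == 0
        assert sex.loc["female", "lowest"] == 1
        for g in ("pct_0", "pct_1"):
            assert sex[g].sum() == pytest.approx(100.0, abs=0.01)

    def test_single_cluster_is_both_lowest_and_highest(self):
        cohort = make_cohort([{"copd", "allergies"}] * 4)
        prof = mm.sociodemographic_profile(cohort, np.zeros(4, dtype=int))
        assert (prof["lowest"] == prof["highest"]).all()

    def test_utilization_means_and_condition_count_bins(self):
        cat = mm.ConditionCatalog.default()
        sets = [set(cat.names[:4]), set(cat.names[:12]), {"copd", "allergies"}]
        util = np.zeros((3, 7), dtype=np.int64)
        util[0, 4] = 2  # 2 GP visits for the first person
        cohort = make_cohort(sets, utilization=util)
        labels = np.array([0, 1, 1])
        means, dist, mean_cond = mm.utilization_and_counts(cohort, labels)
        assert means.loc["gp_visits", 0] == 2.0
        assert mean_cond[0] == 4.0
        assert dist.loc[">=10", 1] == 50.0  # the 12-condition person
        assert dist[0].sum() == pytest.approx(100.0)
        # pooled mean equals the size-weighted average of cluster means
        sizes = np.array([1, 2])
        pooled = (mean_cond[[0, 1]].to_numpy() * sizes).sum() / 3
        assert mean_cond["all"] == pytest.approx(pooled)

    def test_cluster_profiles_bundle(self, small_cohort=None):
        cohort = make_cohort([{"copd", "allergies"}] * 6 + [{"depression", "anxiety"}] * 4)
        labels = np.array([0] * 6 + [1] * 4)
        prof = mm.cluster_profiles(cohort, labels)
        assert prof.cluster_sizes.tolist() == [6, 4]
        assert prof.cluster_pct.sum() == pytest.approx(100.0, abs=0.01)
        assert "Cluster sizes" in prof.summary()


def test_round_half_up_rule():
    assert round_half_up(2.605) == 2.61
    assert round_half_up(2.604) == 2.60
    assert round_half_up(640.5, 0) == 641.0
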