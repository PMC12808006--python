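import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import mmclust as mm
from mmclust import oracle
from mmclust.errors import InitializationError
from mmclust.kmeans import _run_rng


def test_two_cluster_worked_example(tiny_1d, tiny_result):
    assert tiny_result.wcss == pytest.approx(1.0)
    assert tiny_result.converged
    labels = tiny_result.assignments
    assert labels[0] == labels[1] and labels[2] == labels[3]
    assert labels[0] != labels[2]
    tiny_result.validate(tiny_1d.reshape(-1, 1))
    # matches the exhaustive enumeration of all 2-partitions
    best_wcss, _, _ = oracle.best_two_partition_1d(tiny_1d)
    assert best_wcss == pytest.approx(1.0)


def test_every_start_reaches_global_optimum_on_tiny_instance(tiny_1d):
    # all 6 distinct initializations converge to the same WCSS-1 partition
    from itertools import combinations

    for i, j in combinations(range(4), 2):
        res = mm.hartigan_wong(tiny_1d, 2, [[tiny_1d[i]], [tiny_1d[j]]])
        assert res.wcss == pytest.approx(1.0)


def test_k_equals_n_gives_zero_wcss():
    X = np.array([[0.0], [2.0], [5.0], [9.0]])
    res = mm.hartigan_wong(X, 4, X)
    assert res.wcss == 0.0
    assert sorted(res.assignments.tolist()) == [0, 1, 2, 3]


def test_descent_below_initial_voronoi_partition():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(60, 3))
    C0 = X[:4]
    res = mm.hartigan_wong(X, 4, C0)
    # Voronoi-partition WCSS of the initialization (about block means)
    d = ((X[:, None, :] - C0[None]) ** 2).sum(axis=2)
    lab0 = d.argmin(axis=1)
    w0 = sum(
        ((X[lab0 == g] - X[lab0 == g].mean(axis=0)) ** 2).sum()
        for g in range(4) if (lab0 == g).any()
    )
    assert res.wcss <= w0 + 1e-9


def test_duplicate_initial_centroids_rejected():
    X = np.arange(10.0)
    with pytest.raises(InitializationError):
        mm.hartigan_wong(X, 2, [[3.0], [3.0]])


def test_k_larger_than_n_rejected():
    with pytest.raises(ValueError):
        mm.best_of_starts(np.arange(3.0), 5)


def test_result_invariants_on_random_data():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(200, 6))
    res = mm.best_of_starts(X, 5, n_starts=5, rng=np.random.default_rng(1))
    res.validate(X)  # non-empty clusters, centroid means, WCSS consistency


def test_single_start_reduces_to_one_hartigan_wong_call():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(50, 2))
    res = mm.best_of_starts(X, 3, n_starts=1, rng=np.random.default_rng(7))
    # replay the same initialization draw
    idx = np.random.default_rng(7).choice(50, size=3, replace=False)
    ref = mm.hartigan_wong(X, 3, X[idx])
    assert res.wcss == ref.wcss
    assert np.array_equal(res.assignments, ref.assignments)


def test_wcss_non_increasing_in_number_of_starts():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(80, 4))
    prev = np.inf
    for n_starts in (1, 5, 15):
        res = mm.best_of_starts(X, 4, n_starts=n_starts, rng=np.random.default_rng(11))
        assert res.wcss <= prev + 1e-12
        prev = res.wcss


def test_permutation_equivariance():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(70, 3))
    C0 = X[[3, 40, 66]]
    base = mm.hartigan_wong(X, 3, C0)
    perm = rng.permutation(70)
    permuted = mm.hartigan_wong(X[perm], 3, C0)
    matched = mm.match_clusters(base.assignments[perm], permuted.assignments, 3)
    assert np.array_equal(matched[permuted.assignments], base.assignments[perm])


class TestStabilityProtocol:
    def test_unique_optimum_recurs_in_every_run(self):
        rng = np.random.default_rng(0)
        X = np.vstack(
            [rng.normal(0, 0.3, size=(100, 2)), rng.normal(8, 0.3, size=(100, 2))]
        )
        report = mm.stability_protocol(X, 2, n_runs=20, n_starts=3, seed=4)
        assert report.min_count == 20
        assert not report.extended
        assert report.n_runs_total == 20
        assert report.best.wcss == pytest.approx(min(report.run_wcss))

    def test_single_run_with_zero_threshold_is_accepted(self):
        X = np.random.default_rng(1).normal(size=(30, 2))
        report = mm.stability_protocol(
            X, 2, n_runs=1, recurrence_threshold=0, n_starts=2, seed=0
        )
        assert report.n_runs_total == 1
        assert not report.extended

    def test_flat_jittered_data_triggers_extension(self):
        rng = np.random.default_rng(6)
        X = np.ones((40, 3)) + rng.normal(0, 1e-9, size=(40, 3))
        report = mm.stability_protocol(
            X, 3, n_runs=8, recurrence_threshold=8, extension_runs=5,
            n_starts=1, seed=2,
        )
        assert report.extended
        assert report.n_runs_total == 13

    def test_protocol_is_deterministic_and_order_independent(self):
        X = np.random.default_rng(9).normal(size=(100, 4))
        r1 = mm.stability_protocol(X, 3, n_runs=6, n_starts=3, seed=12)
        r2 = mm.stability_protocol(X, 3, n_runs=6, n_starts=3, seed=12)
        assert r1.run_wcss == r2.run_wcss
        assert np.array_equal(r1.best.assignments, r2.best.assignments)
        # substreams are counter-derived, not sequential
        a = _run_rng(12, 3).integers(0, 2**32)
        b = _run_rng(12, 3).integers(0, 2**32)
        assert a == b


@pytest.mark.parametrize("k", [2, 3])
def test_protocol_attains_exhaustive_global_optimum_small_n(k):
    rng = np.random.default_rng(100 + k)
    for _ in range(5):
        n = int(rng.integers(5, 9))
        X = rng.normal(size=(n, 2))
        report = mm.stability_protocol(
            X, k, n_runs=5, recurrence_threshold=0, n_starts=5, seed=int(rng.integers(1000))
        )
        best, _ = oracle.global_minimum_wcss(X, k)
        assert report.best.wcss == pytest.approx(best, rel=1e-9)


def test_planted_recovery_on_separated_cohort(small_cohort):
    cohort, labels = small_cohort
    design = mm.build_design(cohort)
    model = mm.WeightedKMeans(
        n_clusters=3, n_runs=8, n_starts=4, recurrence_threshold=2,
        extension_runs=8, random_state=0,
    ).fit(design)
    assert adjusted_rand_score(labels, model.labels_) >= 0.95
    assert np.array_equal(model.predict(design), model.labels_)


def test_estimator_follows_sklearn_conventions(small_cohort):
    cohort, _ = small_cohort
    from sklearn.pipeline import Pipeline
    import pandas as pd

    X = pd.concat([cohort.conditions, cohort.utilization], axis=1).to_numpy(float)
    pipe = Pipeline(
        [
            ("scale", mm.DomainBalancedScaler()),
            ("cluster", mm.WeightedKMeans(n_clusters=3, n_runs=4, n_starts=3,
                                          recurrence_threshold=0, extension_runs=0,
                                          random_state=1)),
        ]
    )
    labels = pipe.fit_predict(X)
    assert labels.shape == (cohort.n,)
    assert set(labels) == {0, 1, 2}
    params = pipe.get_params()
    assert params["cluster__n_clusters"] == 3
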