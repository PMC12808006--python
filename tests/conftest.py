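import numpy as np
import pytest

import mmclust as mm


@pytest.fixture(scope="session")
def small_cohort():
    """Well-separated 3-cluster cohort, n=300, used across modules."""
    spec = mm.well_separated_spec(n=300, seed=42)
    spec.clusters = spec.clusters[:3]
    total = sum(c.mixing_proportion for c in spec.clusters)
    for c in spec.clusters:
        c.mixing_proportion /= total
    cohort, labels = mm.generate_cohort(spec)
    return cohort, labels


@pytest.fixture(scope="session")
def tiny_1d():
    """The {0, 1, 9, 10} worked example: optimal k=2 split has WCSS 1.0."""
    return np.array([0.0, 1.0, 9.0, 10.0])


@pytest.fixture(scope="session")
def tiny_result(tiny_1d):
    return mm.hartigan_wong(tiny_1d, 2, initial_centroids=[[0.0], [9.0]])
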