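import numpy as np
import pytest

from typiselect.ihc import CaseRecord


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def random_patterns():
    """20 random binary patterns of length 12 for distance-matrix oracles."""
    g = np.random.default_rng(7)
    return g.integers(0, 2, size=(20, 12)).astype(np.int8)


@pytest.fixture(scope="session")
def two_cluster_coords():
    """Two well-separated 3-D Gaussian clusters of 30 points each."""
    g = np.random.default_rng(42)
    a = g.normal(0, 1.0, size=(30, 3)) + np.array([-4.0, 0, 0])
    b = g.normal(0, 1.0, size=(30, 3)) + np.array([+4.0, 0, 0])
    coords = np.vstack([a, b])
    labels = np.array([0] * 30 + [1] * 30)
    return coords, labels


@pytest.fixture(scope="session")
def toy_cases():
    """Nine cases, three subtypes, hand-specified stain sets."""
    sets = [
        {"CD20", "CD3"}, {"CD20", "CD3", "CD10"}, {"CD20", "CD3", "PD1"},
        {"CD20", "BCL2"}, {"CD20", "BCL2", "BCL6"}, {"CD20", "BCL2", "MUM1"},
        {"CD30", "CD15"}, {"CD30", "CD15", "PAX5"}, {"CD30", "CD15", "fascin"},
    ]
    return [
        CaseRecord(case_id=f"c{i}", subtype=i // 3, stains=frozenset(s.lower() for s in s_))
        for i, s_ in enumerate(sets)
    ]
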