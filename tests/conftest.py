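import numpy as np
import pytest

from codivergence.data import AllelePattern, ComparisonCollection, ComparisonData
from codivergence.likelihood import MutationModel, PairDemography


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def model():
    return MutationModel(pi=0.5)


@pytest.fixture
def skewed_model():
    return MutationModel(pi=0.3)


@pytest.fixture
def demog():
    return PairDemography(div_time=0.01, N_root=0.002, N_d1=0.0025, N_d2=0.0015)


@pytest.fixture
def small_data():
    """A tiny hand-built comparison with constant and variable patterns."""
    patterns = [
        AllelePattern(4, 0, 4, 0, 10),
        AllelePattern(4, 4, 4, 4, 8),
        AllelePattern(4, 1, 4, 0, 3),
        AllelePattern(4, 2, 4, 3, 2),
        AllelePattern(3, 1, 4, 2, 1),
    ]
    return ComparisonData(label="toy", patterns=patterns)


@pytest.fixture
def small_collection(small_data):
    other = ComparisonData(
        label="toy2",
        patterns=[
            AllelePattern(3, 0, 3, 0, 5),
            AllelePattern(3, 2, 3, 1, 2),
            AllelePattern(3, 3, 3, 3, 4),
        ],
    )
    return ComparisonCollection([small_data, other])
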