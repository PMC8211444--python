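import numpy as np
import pytest

from mmsdina import (
    ItemParameters,
    MultiStrategyQMatrix,
    ResponseMatrix,
    SimulationDesign,
    simulate_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def small_qmatrix():
    """Two distinct strategies, 4 items, 2 attributes."""
    q1 = np.array([[1, 0], [0, 1], [1, 1], [1, 0]])
    q2 = np.array([[0, 1], [1, 0], [0, 1], [1, 1]])
    return MultiStrategyQMatrix.from_strategies([q1, q2])


@pytest.fixture
def small_params():
    s = np.full((4, 2), 0.25)
    g = np.full((4, 2), 0.15)
    return ItemParameters(s, g)


@pytest.fixture
def tiny_dataset():
    """A 40-examinee two-strategy dataset with its ground truth."""
    q1 = np.array([[1, 0], [0, 1], [1, 1], [1, 0]])
    q2 = np.array([[0, 1], [1, 0], [0, 1], [1, 1]])
    qmat = MultiStrategyQMatrix.from_strategies([q1, q2])
    design = SimulationDesign(model="mmsdina", N=40, qmatrix=qmat,
                              replications=1, rng_seed=99)
    return simulate_dataset(design, 0)
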