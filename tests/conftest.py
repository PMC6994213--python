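import numpy as np
import pytest

from dropexplore.core_data import (
    BehaviorObservation,
    ExperimentRecord,
    ExplorationDataset,
    ObservationBounds,
    normalize_formulation,
)


def make_dataset(X, Y, goals=None) -> ExplorationDataset:
    """Build a dataset from arrays of raw formulation weights and observations."""
    ds = ExplorationDataset()
    for i, (x, y) in enumerate(zip(X, Y)):
        goal = None if goals is None else goals[i]
        ds.append(
            ExperimentRecord(
                index=i,
                formulation=normalize_formulation(x),
                observation=BehaviorObservation(max(float(y[0]), 0.0), max(float(y[1]), 0.0)),
                goal=goal,
                seed=0,
            )
        )
    return ds


@pytest.fixture
def bounds() -> ObservationBounds:
    return ObservationBounds()


@pytest.fixture
def linear_dataset():
    """50 noise-free points from an exact linear map obs = A @ ratios + b."""
    rng = np.random.default_rng(11)
    X = rng.dirichlet(np.ones(4), 50)
    A = np.array([[1.0, 2.0, 0.5, 3.0], [2.0, 0.3, 1.5, 0.7]])
    b = np.array([0.5, 1.0])
    Y = X @ A.T + b
    return make_dataset(X, Y), A, b
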