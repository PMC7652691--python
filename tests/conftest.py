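import numpy as np
import pytest

from corisk.cohort import CohortMatrix


@pytest.fixture
def toy_cohort() -> CohortMatrix:
    """Six patients, three comorbidities, both outcome classes."""
    X = np.array([
        [1, 0, 0],
        [1, 1, 0],
        [0, 1, 1],
        [0, 0, 0],
        [1, 1, 1],
        [0, 0, 1],
    ])
    outcome = np.array([1, 1, 1, 0, 0, 0])
    ids = [f"p{i}" for i in range(6)]
    return CohortMatrix(ids, outcome, X, ["A", "B", "C"])


def make_cohort(X, outcome, names=None) -> CohortMatrix:
    X = np.asarray(X)
    names = names or [f"C{j}" for j in range(X.shape[1])]
    ids = [f"p{i}" for i in range(X.shape[0])]
    return CohortMatrix(ids, np.asarray(outcome), X, names)
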