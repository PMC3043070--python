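import numpy as np
import pytest

from mirmint.io import ExpressionMatrix
from mirmint.preprocess import preprocess_mirna
from mirmint.simulate import CohortConfig, generate_cohort, replicate_groups


@pytest.fixture
def small_matrix():
    return ExpressionMatrix(
        ["f1", "f2", "f3"],
        ["s1", "s2", "s3", "s4"],
        np.array(
            [
                [1.0, 2.0, 3.0, 4.0],
                [4.0, 4.0, 4.0, 4.0],
                [8.0, 2.0, 1.0, 16.0],
            ]
        ),
        scale="linear",
        detection=np.array(
            [
                [True, True, True, True],
                [True, False, False, False],
                [False, False, False, False],
            ]
        ),
    )


@pytest.fixture(scope="session")
def null_cohort():
    """A 60-sample cohort with no planted structure."""
    cfg = CohortConfig(
        n_samples=60,
        n_mirna=100,
        n_mrna=200,
        replicates=2,
        subtype_proportions={"basal-like": 0.5, "luminal-A": 0.5},
        seed=7,
    )
    return cfg, generate_cohort(cfg)


def prep(mirna):
    """Standard miRNA preprocessing used across integration tests."""
    return preprocess_mirna(mirna, replicate_groups(mirna))
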