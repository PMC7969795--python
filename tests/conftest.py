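import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from omifuse.omics_io import ClinicalTable, ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    """3 tumor samples x 4 features with hand-picked values."""
    values = np.array(
        [
            [1.0, 0.0, 2.0, 5.0],
            [3.0, 1.0, 2.0, 5.0],
            [5.0, 0.5, 2.0, 7.0],
        ]
    )
    ids = ["TCGA-AA-0001-01A", "TCGA-AA-0002-01A", "TCGA-AA-0003-01A"]
    return ExpressionMatrix(values, ids, ["f1", "f2", "f3", "f4"], "gene")


@pytest.fixture
def six_subject_clinical():
    """Hand dataset with a tied death/censoring time and late censoring."""
    return ClinicalTable(
        [f"s{i}" for i in range(6)],
        time=[2.0, 5.0, 5.0, 5.0, 8.0, 11.0],
        event=[1, 1, 1, 0, 1, 0],
    )


def random_scores(rng, n, d, layer="gene"):
    from omifuse.preprocess import FeatureScores

    scores = rng.normal(size=(n, d))
    # descending positive eigenvalues, as KPCA would report
    evals = np.sort(rng.uniform(0.5, 2.0, size=d))[::-1]
    return FeatureScores(scores, [f"s{i}" for i in range(n)], evals, layer)
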