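import numpy as np
import pytest

from geneswarm import LabeledExpressionDataset, SyntheticSpec, generate
from geneswarm.prefilter import normalize, select_top_k, t_test_rank


@pytest.fixture(scope="session")
def fixture_dataset():
    """The default synthetic fixture: 500 genes, 20+20 samples, 5 planted
    genes at effect size 2."""
    data, planted = generate(SyntheticSpec())
    return data, planted


@pytest.fixture(scope="session")
def reduced_fixture(fixture_dataset):
    """The fixture after normalisation and the top-50 t-test prefilter, with
    the positions of the planted genes inside the reduced space."""
    data, planted = fixture_dataset
    work = normalize(data)
    top = select_top_k(t_test_rank(work), 50)
    reduced = work.restrict_genes(top)
    planted_positions = np.array(
        [1 if g in set(planted) else 0 for g in top], dtype=np.uint8
    )
    return reduced, planted_positions


@pytest.fixture(scope="session")
def small_dataset():
    """A small, cheap two-class dataset for pipeline-level tests."""
    data, planted = generate(
        SyntheticSpec(n_per_class=(10, 10), n_genes=80, n_informative=3, seed=7)
    )
    return data, planted


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def six_sample_dataset():
    """Fixed 6-sample, 2-gene dataset for fold-by-fold LOOCV checks."""
    matrix = np.array(
        [
            [0.2, -0.1, 0.4, 1.1, 0.9, 1.3],
            [-0.3, 0.1, -0.2, 0.8, 1.2, 1.0],
        ]
    )
    return LabeledExpressionDataset(
        matrix=matrix,
        gene_ids=["g1", "g2"],
        labels=np.array(["a", "a", "a", "b", "b", "b"]),
    )
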