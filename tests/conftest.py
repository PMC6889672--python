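import numpy as np
import pytest

from irfmda.synthetic import make_planted_world, make_toy_paper_instances


@pytest.fixture(scope="session")
def toys():
    return make_toy_paper_instances()


@pytest.fixture(scope="session")
def small_world():
    """Strong-signal micro world: fast to fit, clearly separable blocks."""
    return make_planted_world(
        nd=8, nm=12, groups=2, p_in=0.7, p_out=0.05, seed=42
    )


@pytest.fixture(scope="session")
def cheap_config():
    """Pipeline settings small enough for per-test fits."""
    from irfmda.pipeline import PipelineConfig

    return PipelineConfig(k=None, rf_ntree=60, seed=5)


def planted_feature_dataset(
    n: int = 500,
    p: int = 100,
    n_informative: int = 10,
    seed: int = 0,
    shuffle_labels: bool = False,
):
    """Balanced binary labels with the first ``n_informative`` columns
    carrying signal (half label, half uniform noise) and the rest pure noise."""
    from irfmda.dataset_builder import LabeledDataset, PairSample

    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    X = rng.uniform(0.0, 1.0, (n, p))
    for j in range(min(n_informative, p)):
        X[:, j] = 0.5 * y + 0.5 * rng.uniform(0.0, 1.0, n)
    if shuffle_labels:
        y = rng.permutation(y)
    samples = tuple(PairSample(i, i, int(y[i])) for i in range(n))
    names = tuple(f"f{j:03d}" for j in range(p))
    return LabeledDataset(samples, X, names)
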