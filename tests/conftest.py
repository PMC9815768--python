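import numpy as np
import pytest

from rbfregimes.datasets import LabeledDataset, generate_task


@pytest.fixture(scope="session")
def small_task():
    """A modest K=5 task with two irrelevant dimensions (train, test, spec)."""
    return generate_task(K=5, n_samples=1200, n_irrelevant=2, seed=7)


@pytest.fixture(scope="session")
def tiny_train():
    """A 300-point 2-D training set for fast regime contracts."""
    train, _, _ = generate_task(K=2, n_samples=430, n_irrelevant=0, seed=11)
    return train


def make_blobs_dataset(centers, labels, n_per, sigma, seed=0):
    """Deterministic well-separated blobs for constructed regime instances."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for c, lab in zip(centers, labels):
        X.append(np.asarray(c) + rng.normal(0, sigma, size=(n_per, len(c))))
        y.append(np.full(n_per, lab))
    return LabeledDataset(
        features=np.vstack(X),
        labels=np.concatenate(y).astype(int),
        role="train",
        relevant_range=None,
    )
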