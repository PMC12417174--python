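import numpy as np
import pytest

from skipgru import (
    SkipGRUConfig,
    SyntheticSpec,
    TabularDataset,
    apply_minmax,
    fit_minmax,
    generate,
)


@pytest.fixture
def toy_dataset():
    """6-row, 3-feature dataset with one zero-coded column."""
    features = np.array([
        [2.0, 10.0, 1.0],
        [4.0, 0.0, 2.0],
        [6.0, 30.0, 3.0],
        [3.0, 20.0, 4.0],
        [5.0, 40.0, 5.0],
        [4.5, 25.0, 6.0],
    ])
    return TabularDataset(
        features=features,
        labels=np.array([0, 1, 0, 1, 0, 1]),
        feature_names=("a", "b", "c"),
        class_names=("neg", "pos"),
        missing_columns=frozenset({"b"}),
    )


def planted_dataset(n=300, d=8, informative=(1, 3, 6), effect=2.0, seed=0,
                    normalize=True, **kwargs):
    """Class-conditional Gaussian data with known informative features."""
    spec = SyntheticSpec(
        n_samples=n, n_features=d, informative=tuple(informative),
        effect_size=effect, **kwargs,
    )
    ds, truth = generate(spec, seed=seed)
    if normalize:
        ds = apply_minmax(ds, fit_minmax(ds))
    return ds, truth


@pytest.fixture
def tiny_config():
    """Smallest sensible training configuration for fast unit tests."""
    return SkipGRUConfig(
        hidden_size=4, gate_hidden=4, dropout=0.0, weight_decay=0.0,
        learning_rate=0.01, batch_size=16, epochs=3,
    )
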