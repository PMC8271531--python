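import numpy as np
import pytest

from whalefs.data import Dataset


def sphere(x):
    return float(np.sum(x * x))


@pytest.fixture
def sphere_fn():
    return sphere


@pytest.fixture
def tiny_categorical_dataset():
    """Four instances, two binary categorical features, two classes."""
    X = np.array(
        [["a", "x"], ["a", "y"], ["b", "x"], ["b", "y"]], dtype=object
    )
    y = np.array([0, 0, 1, 1])
    return Dataset(
        X=X,
        y=y,
        feature_names=["f0", "f1"],
        feature_kinds=["categorical", "categorical"],
        name="toy",
    )


def make_continuous_dataset(n=200, separation=6.0, k_noise=0, seed=0):
    """Labels follow the sign of feature 0; optional pure-noise columns."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    x0 = rng.standard_normal(n) + np.where(y == 1, separation / 2, -separation / 2)
    cols = [x0] + [rng.standard_normal(n) for _ in range(k_noise)]
    X = np.column_stack(cols)
    names = [f"f{j}" for j in range(X.shape[1])]
    return Dataset(
        X=X, y=y, feature_names=names,
        feature_kinds=["continuous"] * X.shape[1], name="signed",
    )
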