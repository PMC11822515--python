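import numpy as np
import pandas as pd
import pytest

from wormqsar.curation import split_dataset
from wormqsar.data import DescriptorMatrix
from wormqsar.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def benchmark_dataset():
    """Default synthetic benchmark: 449 compounds x 300 descriptors, 8 planted."""
    return generate_dataset(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def benchmark_split(benchmark_dataset):
    """Modeling/test split of the benchmark, mirroring the 302/147 partition."""
    return split_dataset(benchmark_dataset.descriptor_matrix, 147, seed=1)


@pytest.fixture()
def tiny_separable():
    """A small linearly separable two-class table (one informative column)."""
    rng = np.random.default_rng(0)
    n = 40
    y = np.repeat([1, 0], n // 2)
    X = pd.DataFrame({
        "signal": np.where(y == 1, 2.0, -2.0) + rng.normal(0, 0.1, n),
        "junk": rng.normal(size=n),
    }, index=pd.Index([f"c{i}" for i in range(n)], name="compound_id"))
    return DescriptorMatrix(X, pd.Series(y, index=X.index))


@pytest.fixture()
def xor_dataset():
    """Labels depend on the sign product of two columns; not additively separable."""
    rng = np.random.default_rng(1)
    n = 200
    a = rng.choice([-1.0, 1.0], n) + rng.normal(0, 0.2, n)
    b = rng.choice([-1.0, 1.0], n) + rng.normal(0, 0.2, n)
    y = (np.sign(a) * np.sign(b) > 0).astype(int)
    X = pd.DataFrame({"a": a, "b": b},
                     index=pd.Index([f"c{i}" for i in range(n)], name="compound_id"))
    return DescriptorMatrix(X, pd.Series(y, index=X.index))
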