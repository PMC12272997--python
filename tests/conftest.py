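import numpy as np
import pytest

from mtoscca.data import DataBlock, FeatureMatrix, standardize_block


def make_block(n=20, p=5, q=7, M=2, seed=0, labels=False, standardized=True):
    """Random dense DataBlock for solver/metric tests."""
    rng = np.random.default_rng(seed)
    ids = [f"s{i}" for i in range(n)]
    X = FeatureMatrix(rng.standard_normal((n, p)), ids,
                      [f"x{j}" for j in range(p)])
    Ys = tuple(FeatureMatrix(rng.standard_normal((n, q)), ids,
                             [f"y{m}_{j}" for j in range(q)])
               for m in range(M))
    lab = rng.integers(0, 2, size=n) if labels else None
    if lab is not None and len(np.unique(lab)) < 2:
        lab[0] = 1 - lab[0]
    block = DataBlock(X, Ys, lab)
    return standardize_block(block) if standardized else block


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_block():
    return make_block()
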