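import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


def random_discrete_genotype(n, n_interactions, rng):
    from grnmod import Genotype

    mat = np.zeros(n * n, dtype=np.int8)
    pos = rng.choice(n * n, size=n_interactions, replace=False)
    mat[pos] = rng.choice(np.array([-1, 1], dtype=np.int8), size=n_interactions)
    return Genotype(mat.reshape(n, n))
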