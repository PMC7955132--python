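import numpy as np
import pandas as pd
import pytest

from fusenet.matrix import ExpressionMatrix


def make_matrix(values, genes=None, samples=None, biotype="protein_coding", condition="normal"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    biotypes = pd.Series([biotype] * len(genes), index=genes)
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        biotypes=biotypes,
        condition=condition,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_matrix(rng):
    return make_matrix(rng.lognormal(3.0, 1.0, size=(10, 8)))
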