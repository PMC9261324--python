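import numpy as np
import pandas as pd
import pytest

from agecoex.containers import ExpressionMatrix, TraitTable


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_matrix(values, scale_tag="normalized_intensity", genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), scale_tag)


@pytest.fixture
def small_matrix(rng):
    return make_matrix(rng.standard_normal((10, 20)))


@pytest.fixture
def simple_traits():
    ages = [25, 30, 35, 50, 60, 70, 75, 80]
    return TraitTable(
        pd.DataFrame(
            {
                "age": ages,
                "sex": ["F", "M"] * 4,
                "ethnicity": ["e1"] * 4 + ["e2"] * 4,
                "group": ["young"] * 3 + ["middle"] * 2 + ["old"] * 3,
            },
            index=[f"s{j}" for j in range(8)],
        )
    )
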