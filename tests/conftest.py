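import numpy as np
import pandas as pd
import pytest

from iganpath import (GeneratorConfig, fit, final_spec, generate_standardized)


@pytest.fixture(scope="session")
def final_model():
    return final_spec()


@pytest.fixture(scope="session")
def standardized_table():
    """One seeded standardized cohort at the published size."""
    return generate_standardized(GeneratorConfig(n=946, seed=20220909))


@pytest.fixture(scope="session")
def final_fit(final_model, standardized_table):
    return fit(final_model, standardized_table)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def toy_chain_table(n=400, b1=0.5, b2=0.4, seed=7):
    """x -> y -> z chain with standardized coefficients b1, b2."""
    r = np.random.default_rng(seed)
    x = r.standard_normal(n)
    y = b1 * x + np.sqrt(1 - b1 ** 2) * r.standard_normal(n)
    z = b2 * y + np.sqrt(1 - b2 ** 2) * r.standard_normal(n)
    return pd.DataFrame({"x": x, "y": y, "z": z})
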