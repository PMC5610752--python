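import numpy as np
import pandas as pd
import pytest

from qsarforge import DescriptorTable
from qsarforge.synth import SynthConfig, generate


@pytest.fixture(scope="session")
def default_dataset():
    """Study-shaped synthetic dataset: 35 compounds, 200-descriptor pool."""
    return generate(SynthConfig(seed=3))


@pytest.fixture(scope="session")
def clean_dataset():
    """No nuisance columns: 35 compounds, 100 descriptors, 5 informative."""
    return generate(SynthConfig(n_compounds=35, n_descriptors=100,
                                k_informative=5, n_constant=0,
                                n_near_constant=0, n_collinear_pairs=0,
                                noise_sd=0.2, seed=17))


@pytest.fixture(scope="session")
def noiseless_dataset():
    return generate(SynthConfig(n_compounds=30, n_descriptors=20,
                                k_informative=4, n_constant=0,
                                n_near_constant=0, n_collinear_pairs=0,
                                noise_sd=0.0, seed=5))


@pytest.fixture()
def tiny_table():
    """Hand-built 6-compound, 3-descriptor table."""
    rng = np.random.default_rng(0)
    X = rng.normal(size=(6, 3))
    y = 1.0 + 2.0 * X[:, 0] - 0.5 * X[:, 1] + rng.normal(0, 0.1, size=6)
    ids = [f"C{i}" for i in range(6)]
    return DescriptorTable(
        pd.DataFrame(X, index=ids, columns=["a", "b", "c"]),
        pd.Series(y, index=ids),
    )
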