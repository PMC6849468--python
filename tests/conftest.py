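import numpy as np
import pandas as pd
import pytest

from wheatnue.datasets import (
    load_reference_fits,
    load_reference_harvest,
    load_reference_vegetative,
)


@pytest.fixture(scope="session")
def reference_fits() -> pd.DataFrame:
    return load_reference_fits()


@pytest.fixture(scope="session")
def reference_harvest() -> pd.DataFrame:
    return load_reference_harvest()


@pytest.fixture(scope="session")
def reference_vegetative() -> pd.DataFrame:
    return load_reference_vegetative()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
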