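import numpy as np
import pandas as pd
import pytest

from dwmap import ValueSet, make_reference_fixture


@pytest.fixture(scope="session")
def ref() -> pd.DataFrame:
    """The packaged 27-health-state reference table."""
    return make_reference_fixture()


@pytest.fixture(scope="session")
def study2_means(ref) -> pd.Series:
    """Web-pilot state mean utilities, keyed by health state id."""
    return pd.Series(
        ref["mean_utility_study2"].to_numpy(dtype=float), index=ref["id"].astype(int)
    )


@pytest.fixture(scope="session")
def study1(ref) -> pd.DataFrame:
    """The four written-pilot states with their mean utilities and DWs."""
    return ref[ref["mean_utility_study1"].notna()].reset_index(drop=True)


@pytest.fixture()
def toy_value_set() -> ValueSet:
    """Constant 0.1, every level-2 decrement 0.05, level-3 0.2, no indicators."""
    decs = {(d, 2): 0.05 for d in range(1, 6)}
    decs.update({(d, 3): 0.2 for d in range(1, 6)})
    return ValueSet(name="toy", intercept_constant=0.1, level_decrements=decs)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20170206)
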