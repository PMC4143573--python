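import numpy as np
import pytest

import thermoscreen as ts


@pytest.fixture
def trio():
    return ts.default_strain_trio()


@pytest.fixture
def roles():
    return {"tolerant": "tolerant", "reference": "reference", "sensitive": "sensitive"}


@pytest.fixture
def exponential_curve():
    """Zero-noise exponential curve: mu = ln2/1.5 -> T_d = 1.5 h."""
    mu = np.log(2) / 1.5
    t = np.linspace(0, 6, 13)
    return ts.GrowthCurve(
        strain="s", temperature="low", times=t, od=0.1 * np.exp(mu * t)
    )
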