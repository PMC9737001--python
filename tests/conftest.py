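import math

import numpy as np
import pytest

from hospitalflow import default_config


@pytest.fixture(scope="session")
def cfg():
    """The committed default hospital configuration."""
    return default_config()


@pytest.fixture()
def quiet_cfg():
    """Default hospital with all arrival intensities zeroed (empty system)."""
    c = default_config()
    for k in c.arrival_rates:
        c.arrival_rates[k] = np.zeros((7, 24))
    return c


@pytest.fixture()
def trace_cfg():
    """Deterministic single-pathway config: 3 h ED treatment, no admissions."""
    c = default_config()
    c.ed_treatment_params = (math.log(3.0), 0.0)
    c.admit_probability = np.zeros(5)
    return c
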