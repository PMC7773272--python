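import numpy as np
import pytest

import itcvar as iv


@pytest.fixture
def nano_errors():
    """NanoITC basic error parameters used as the reference conditions."""
    return iv.ErrorParams(sigma_b=0.1771, sigma_p=0.00309, sigma_v=0.0214)


@pytest.fixture
def saturated_setup():
    """Tight-binding excess-titrand configuration: constant expected heat."""
    config = iv.TitrationConfig(
        C_syr=5.0, C_cell=5.0, injection_volumes=(10.0,) * 25
    )
    rxn = iv.ReactionParams(Ka=1e9, dH=-40.0)
    return config, rxn


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
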