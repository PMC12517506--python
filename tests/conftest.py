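import numpy as np
import pytest

from lamelliflow.params import ParameterSet, build_reference_config


@pytest.fixture(scope="session")
def ref_params() -> ParameterSet:
    return build_reference_config()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def quiet_params(**overrides) -> ParameterSet:
    """Reference parameters with all stochastic kinetics switched off;
    useful for pure-mechanics checks."""
    base = dict(k_n_A=0.0, k_plus_A=0.0, k_minus_A=0.0, k0_sev=0.0,
                k_plus_ACP=0.0, k_plus_Arp=0.0, k_plus_C=0.0, k0_u_C=0.0,
                motor_bind_per_head=0.0)
    base.update(overrides)
    return build_reference_config(**base)
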