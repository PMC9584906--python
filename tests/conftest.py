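import numpy as np
import pytest

from motorlab import NLCParams, SweepSpec, gen_nlc_sweeps


@pytest.fixture(scope="session")
def wt_params() -> NLCParams:
    """Wild-type NLC parameter set: alpha 0.032 mV^-1, V_pk -65 mV,
    charge density 12 fC/pF at C_lin = 10 pF."""
    return NLCParams(alpha=0.032, V_pk=-65.0, Q_max=120.0, C_lin=10.0)


@pytest.fixture(scope="session")
def wt_sweeps(wt_params):
    """22 noisy sweeps at the WT parameter set (noise 0.2% of C_lin)."""
    spec = SweepSpec(params=wt_params, v_min=-150, v_max=150, v_step=5,
                     noise_sd=0.02, n_sweeps=22, seed=42)
    return gen_nlc_sweeps(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
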