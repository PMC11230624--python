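import numpy as np
import pytest

from v1energy.simulate import NeuronGroundTruth, SimulationConfig, simulate_grating_session


@pytest.fixture(scope="session")
def noiseless_session():
    """Small noiseless session: two tuned neurons, one non-responsive."""
    config = SimulationConfig(seed=11, n_trials=2, sfs=(0.04, 0.16))
    truths = [
        NeuronGroundTruth(c=0.1, rp=1.0, rn=0.4, theta_pref=90.0, sigma=30.0, sf_pref=0.04),
        NeuronGroundTruth(c=0.0, rp=0.8, rn=0.2, theta_pref=210.0, sigma=25.0, sf_pref=0.16),
        NeuronGroundTruth(c=0.0, rp=0.0, rn=0.0, theta_pref=0.0, sigma=30.0,
                          sf_pref=0.04, responsive=False),
    ]
    traces, protocol, truth = simulate_grating_session(config, truths, return_truth=True)
    return dict(config=config, truths=truths, traces=traces, protocol=protocol, **truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
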