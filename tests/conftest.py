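import numpy as np
import pytest

import paindecode as pdz


@pytest.fixture(scope="session")
def quiet_recording():
    """Near-silent two-channel recording for construction-based tests."""
    rng = np.random.default_rng(0)
    data = 1e-6 * rng.standard_normal((2, 20 * 2000))
    return pdz.LFPRecording(data=data, fs=2000.0)


@pytest.fixture(scope="session")
def small_mechanical_session():
    """A 12-trial high-SNR mechanical session shared across tests."""
    proto = pdz.mechanical_protocol(n_trials=12, seed=101)
    regions, events, ground_truth = pdz.generate_session(proto)
    return proto, regions, events, ground_truth


def random_stable_params(rng: np.random.Generator) -> pdz.SSMParams:
    """A random stable, well-conditioned parameter set."""
    A = rng.normal(size=(3, 3))
    return pdz.SSMParams(
        a=rng.uniform(-0.95, 0.95),
        c=rng.normal(size=3),
        d=rng.normal(size=3),
        sigma2=rng.uniform(0.3, 2.0),
        Sigma=A @ A.T + 0.5 * np.eye(3),
    )
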