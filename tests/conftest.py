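import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_noisy_series():
    """Stationary 3-node network at 10 dB, short, for cheap end-to-end runs."""
    import pfconn

    spec = pfconn.SyntheticNetworkSpec(
        n_nodes=3, n_timepoints=80, snr_db=10.0, seed=42
    )
    series, truth = pfconn.generate(spec)
    return series, truth
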