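import numpy as np
import pytest

import agnckit as ak


@pytest.fixture(scope="session")
def default_irf():
    """Noiseless Gaussian IRF on the default 4096-channel axis."""
    return ak.simulate_irf(ak.DecaySimConfig(), noiseless=True)


@pytest.fixture(scope="session")
def mono_decay_bright():
    """One Poisson-sampled mono-exponential decay, 1e6 counts, tau 3.42 ns."""
    return ak.simulate_decay(ak.DecaySimConfig(total_counts=1e6, seed=42))


@pytest.fixture(scope="session")
def tres_flat():
    """Relaxation-free wavelength-stepped dataset (band static in time)."""
    cfg = ak.RelaxationSimConfig(
        total_shift=0.0,
        decay=ak.DecaySimConfig(n_channels=2048, channel_width=0.032,
                                total_counts=1e6, seed=7),
    )
    return cfg, ak.simulate_tres(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
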