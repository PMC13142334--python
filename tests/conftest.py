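import numpy as np
import pytest

from musclekit.core import StimulationProtocol
from musclekit.synthetic import TwitchModelParams, gen_trace


@pytest.fixture(scope="session")
def twitch_protocol():
    return StimulationProtocol.twitch()


@pytest.fixture(scope="session")
def ff_protocol():
    return StimulationProtocol.force_frequency()


@pytest.fixture(scope="session")
def noise_free_twitch(twitch_protocol):
    """Noise-free synthetic twitch trace (deflection) + ground truth."""
    params = TwitchModelParams(peak_active_force=1.2, tau_rise=0.03,
                               tau_decay=0.15, passive_baseline=0.5,
                               noise_sd=0.0, post_stiffness=1.0, seed=0)
    trace, gt = gen_trace(params, twitch_protocol)
    return params, trace, gt


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
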