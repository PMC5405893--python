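import numpy as np
import pytest

from naplines.gaborjet import JetGridConfig, audit_triplets
from naplines.geometry import StimulusConfig, default_specs, generate_stimulus_set
from naplines.render import RenderConfig


@pytest.fixture(scope="session")
def stimulus_set():
    return generate_stimulus_set(StimulusConfig())


@pytest.fixture(scope="session")
def specs():
    return default_specs(StimulusConfig())


@pytest.fixture(scope="session")
def audits(stimulus_set):
    """Full GaborJet audit of the default set (shared: it is the slow step)."""
    return audit_triplets(stimulus_set, RenderConfig(), JetGridConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
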