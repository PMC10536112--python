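import numpy as np
import pytest

from capivid.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """A small jittered phantom with full ground truth, shared across tests."""
    spec = PhantomSpec(
        width=320,
        height=256,
        n_frames=8,
        n_vessels=3,
        blob_features=18,
        jitter_translation=5.0,
        jitter_rotation=1.5,
        noise_sigma=3.0,
        seed=123,
    )
    return generate_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
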