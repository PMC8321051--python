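import numpy as np
import pytest

from mvtrack import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def healthy_phantom():
    """Default healthy phantom (256 px, speckle and jitter on)."""
    frames, truth = generate_phantom(PhantomSpec(mode="healthy", seed=11))
    return frames, truth


@pytest.fixture(scope="session")
def clean_healthy_phantom():
    """Noise-free healthy phantom: deterministic geometry only."""
    frames, truth = generate_phantom(
        PhantomSpec(mode="healthy", speckle_sigma=0.0, jitter_px=0, seed=11)
    )
    return frames, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20260931)
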