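import numpy as np
import pytest

from fluorofuse import DetectorParams, PhantomSpec, generate_dataset


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """A short clean phantom used by several integration tests."""
    return PhantomSpec(seed=1, n_frames=6)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return generate_dataset(small_spec)


@pytest.fixture(scope="session")
def small_detection(small_spec, small_dataset):
    from fluorofuse import detect_sequence

    frames, truth, physio = small_dataset
    params = DetectorParams.for_phantom(small_spec)
    return detect_sequence(frames.frames, params)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
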