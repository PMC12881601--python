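import numpy as np
import pytest

from papcell.phantoms import PhantomSpec, generate_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """120 phantoms at 32 px, two classes; shared across tests (read-only)."""
    spec = PhantomSpec(image_size=32)
    samples, manifest = generate_dataset(
        spec, {"normal": 60, "abnormal": 60}, seed=5)
    return spec, samples, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
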