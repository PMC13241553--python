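import numpy as np
import pytest

from avpseg.labels import DEFAULT_SCHEME
from avpseg.phantom import PhantomSpec, generate_phantom
from avpseg.volume import LabelMap


@pytest.fixture(scope="session")
def scheme():
    return DEFAULT_SCHEME


@pytest.fixture(scope="session")
def small_spec():
    """Fast phantom spec used across tests (~0.2 s to render)."""
    return PhantomSpec.fit_grid((32, 32, 16))


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec.replace(seed=42))


@pytest.fixture(scope="session")
def desk_phantom():
    """Default-geometry phantom at the full desk grid."""
    return generate_phantom(PhantomSpec(seed=42))


def random_label_map(rng, shape=(16, 16, 16), n_blobs=6, scheme=DEFAULT_SCHEME):
    """Blobby random multiclass map for property tests."""
    data = np.zeros(shape, dtype=np.uint8)
    for _ in range(n_blobs):
        c = rng.integers(1, scheme.num_classes)
        center = rng.integers(2, np.array(shape) - 2)
        r = int(rng.integers(1, 4))
        idx = np.indices(shape)
        d2 = sum((idx[i] - center[i]) ** 2 for i in range(3))
        data[d2 <= r * r] = c
    return LabelMap(data, spacing=(1.0, 1.0, 1.0), scheme=scheme)
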