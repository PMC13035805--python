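import numpy as np
import pytest

from amsd import (
    SBS96,
    SpectrumMatrix,
    default_baseline,
    make_fixture_catalog,
)


@pytest.fixture(scope="session")
def catalog():
    """The deterministic synthetic signature catalog (5 signatures over SBS96)."""
    return make_fixture_catalog(seed=0)


@pytest.fixture(scope="session")
def baseline(catalog):
    """30/60/10 mixture of the three backbone signatures."""
    return default_baseline(catalog)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_matrix(rng):
    """5 samples x 96 channels of small random integer counts, all totals > 0."""
    counts = rng.integers(0, 20, size=(5, 96)).astype(float)
    counts[:, 0] += 1  # guarantee positive totals
    return SpectrumMatrix(SBS96, [f"s{i}" for i in range(5)], counts)


def two_channel_matrix(sample_counts, prefix="s"):
    """Helper: a matrix over a 2-channel schema from a list of (c1, c2) counts."""
    from amsd import ChannelSchema

    schema = ChannelSchema("toy2", ("ch1", "ch2"))
    ids = [f"{prefix}{i}" for i in range(len(sample_counts))]
    return SpectrumMatrix(schema, ids, np.array(sample_counts, dtype=float))
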