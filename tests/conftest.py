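import numpy as np
import pytest

from flcs2d import InstrumentModel, PhotonStream, fixture_scheme, simulate_stream


@pytest.fixture(scope="session")
def instrument():
    return InstrumentModel()


@pytest.fixture(scope="session")
def static_dye_stream():
    """Single immobile dye molecule at the focus centre (4.0 ns lifetime)."""
    return simulate_stream(fixture_scheme("dye_only"), duration=1.2, seed=11,
                           static_at_focus=True)


@pytest.fixture(scope="session")
def scheme1_stream_small():
    """Short two-state (70/280 ps, 5 us exchange) trace for unit tests."""
    return simulate_stream(fixture_scheme("scheme1"), duration=6.0, seed=12)


def poisson_two_channel_stream(rate=5e4, duration=2.0, seed=0, lifetime_ns=2.0):
    """Uncorrelated (homogeneous Poisson) two-channel stream."""
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate * duration)
    mac = np.sort(rng.uniform(0, duration, n))
    mic = np.clip(rng.exponential(lifetime_ns, n) + 0.25, 0, 12.287)
    ch = (rng.random(n) < 0.5).astype(np.int8)
    return PhotonStream(mac, mic, ch, duration, {"synthetic": "poisson"})


@pytest.fixture(scope="session")
def poisson_stream():
    return poisson_two_channel_stream(seed=21)
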