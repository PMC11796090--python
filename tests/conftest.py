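import numpy as np
import pytest

from photonstream import EventStream, HeaderInfo


@pytest.fixture
def header():
    return HeaderInfo(
        macro_time_resolution=50e-9,
        micro_time_resolution=50e-9 / 256,
        n_microtime_channels=256,
        source_format="test",
        metadata={"origin": "fixture"},
    )


def make_random_stream(seed, n=200, n_channels=4, marker_fraction=0.05,
                       n_micro=256, max_tick=10**6, metadata=None):
    """Random but valid event stream: sorted macro times, mixed markers."""
    rng = np.random.default_rng(seed)
    macro = np.sort(rng.integers(0, max_tick, size=n)).astype(np.uint64)
    micro = rng.integers(0, n_micro, size=n).astype(np.uint32)
    channels = rng.integers(0, n_channels, size=n).astype(np.uint16)
    etypes = (rng.random(n) < marker_fraction).astype(np.uint8)
    header = HeaderInfo(
        macro_time_resolution=50e-9,
        micro_time_resolution=50e-9 / n_micro,
        n_microtime_channels=n_micro,
        source_format="test",
        metadata=metadata if metadata is not None else {"seed": int(seed)},
    )
    return EventStream(macro, micro, channels, etypes, header)


@pytest.fixture
def random_stream():
    return make_random_stream


@pytest.fixture
def stream5(header):
    """Tiny hand-written 5-event stream used by slicing tests."""
    return EventStream(
        np.array([0, 10, 20, 30, 40], dtype=np.uint64),
        np.array([1, 2, 3, 4, 5], dtype=np.uint32),
        np.array([0, 1, 0, 2, 1], dtype=np.uint16),
        np.zeros(5, dtype=np.uint8),
        header,
    )
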