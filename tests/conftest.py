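import numpy as np
import pytest

from sapm.network import Connection, LatentInput, NetworkModel, RegionSpec, default_network


def make_net(regions, connections, latents):
    return NetworkModel(
        regions=[RegionSpec(name=a.lower(), abbrev=a) for a in regions],
        connections=[Connection(s, t) for s, t in connections],
        latents=[LatentInput(name, tuple(targets)) for name, targets in latents],
    )


@pytest.fixture(scope="session")
def default_net():
    return default_network()


@pytest.fixture
def chain3_net():
    """a -> b -> c driven by one latent into a; no loops, fully identifiable."""
    return make_net(
        ["a", "b", "c"],
        [("a", "b"), ("b", "c")],
        [("int1", ["a"])],
    )


@pytest.fixture
def two_region_net():
    """Latent into a, single edge a -> b."""
    return make_net(["a", "b"], [("a", "b")], [("int1", ["a"])])


@pytest.fixture
def small8_net():
    """4 regions, 8 inter-region connections, one latent (scaled null tests)."""
    return make_net(
        ["a", "b", "c", "d"],
        [
            ("a", "b"),
            ("a", "c"),
            ("a", "d"),
            ("b", "c"),
            ("b", "d"),
            ("c", "d"),
            ("b", "a"),
            ("d", "a"),
        ],
        [("int1", ["a"])],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
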