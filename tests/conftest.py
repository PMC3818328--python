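import pathlib

import numpy as np
import pytest

import vegadct as v

DATA_DIR = pathlib.Path(__file__).parent / "data"


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def evolved_rule_k7():
    """Stored high-fitness genome evolved by the variable-environment GA at
    k=7 (regenerable with scripts/evolve_fixture.py)."""
    return v.read_rule(DATA_DIR / "evolved_rule_k7.txt")


def aligned_promoted_network(base: v.AgentNetwork) -> v.AgentNetwork:
    """A degree-(d+2) network whose first d slots replicate ``base`` —
    the two appended slots feed a promoted rule's silent inputs."""
    N, d = base.N, base.degree
    extra = np.stack(
        [(np.arange(N) + d // 2 + 1) % N, (np.arange(N) - d // 2 - 1) % N],
        axis=1,
    ).astype(np.int32)
    slots = np.concatenate([base.slots, extra], axis=1)
    return v.AgentNetwork(N, d + 2, slots)
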