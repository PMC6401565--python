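import numpy as np
import pytest

from metnetprio.edges import EdgeSet
from metnetprio.hetnet import assemble, build_transition


def random_edge_sets(rng, n_g=30, n_m=20, n_p=10, density=0.15):
    """Random three-layer edge sets for walk/assembly tests."""
    genes = [f"G{i:04d}" for i in range(1, n_g + 1)]
    mets = [f"M{i:04d}" for i in range(1, n_m + 1)]
    phenos = [f"P{i:04d}" for i in range(1, n_p + 1)]

    def intra(part, ids):
        pairs = []
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if rng.random() < density:
                    pairs.append((ids[i], ids[j], float(rng.uniform(0.1, 1.0))))
        return EdgeSet.from_pairs(part, pairs)

    def cross(part, ids_a, ids_b):
        pairs = [
            (a, b, float(rng.uniform(0.1, 1.0)))
            for a in ids_a for b in ids_b if rng.random() < density
        ]
        return EdgeSet.from_pairs(part, pairs)

    return {
        "gg": intra("gg", genes),
        "mm": intra("mm", mets),
        "pp": intra("pp", phenos),
        "gm": cross("gm", genes, mets),
        "gp": cross("gp", genes, phenos),
        "mp": cross("mp", mets, phenos),
    }


def random_hetnet(rng, **kw):
    return assemble(random_edge_sets(rng, **kw))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_net(rng):
    return random_hetnet(rng)


@pytest.fixture
def small_model(small_net):
    return build_transition(small_net, lambda_jump=0.5)
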