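import numpy as np
import pytest

from foldkit import parse_structure
from foldkit.fixtures import make_chain, make_pair


@pytest.fixture(scope="session")
def leu_pair_factory():
    """Parsed two-leucine structure at a given closest heavy-atom separation."""
    cache = {}

    def build(separation):
        if separation not in cache:
            cache[separation] = parse_structure(make_pair("LEU", "LEU", separation))
        return cache[separation]

    return build


@pytest.fixture(scope="session")
def small_protein():
    """A ten-residue mixed chain used by several analyses."""
    text = make_chain(["LEU", "GLU", "VAL", "LYS", "ILE", "SER", "ASP",
                       "LEU", "ARG", "VAL"], spacing=5.5, jitter=0.3, seed=11)
    return parse_structure(text)


def random_rigid_transform(rng):
    """A uniformly random rotation matrix and a translation vector."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    return rot, rng.normal(scale=20.0, size=3)
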