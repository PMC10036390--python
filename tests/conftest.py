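import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ptnet.network import TraitNetwork


def make_net(adjacency, names=None, alpha=0.05, group=None) -> TraitNetwork:
    a = np.asarray(adjacency, dtype=int)
    if names is None:
        names = [chr(ord("A") + i) for i in range(a.shape[0])]
    return TraitNetwork(a, list(names), alpha, group)


def random_adjacency(rng: np.random.Generator, n: int, p: float = 0.4) -> np.ndarray:
    a = (rng.random((n, n)) < p).astype(int)
    a = np.triu(a, 1)
    return a + a.T


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def trait_csv(tmp_path):
    """6 individuals, 3 traits, 2 lakes, one NA cell."""
    p = tmp_path / "traits.csv"
    p.write_text(
        "lake,H,LL,LA\n"
        "A,10.0,5.0,2.0\n"
        "A,12.0,NA,2.5\n"
        "A,11.0,5.5,2.2\n"
        "B,20.0,8.0,4.0\n"
        "B,21.0,8.5,4.1\n"
        "B,19.0,7.5,3.9\n"
    )
    return p
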