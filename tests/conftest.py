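import numpy as np
import pytest

from bayesupertree import _topology as top


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_multree_instance(rng, n_species_max=6, leaves_max=8):
    """Random (species struct, unrooted gene struct, leaf->species ids)."""
    n_sp = int(rng.integers(2, n_species_max + 1))
    s = top.random_rooted(range(n_sp), rng)
    n_leaves = int(rng.integers(3, leaves_max + 1))
    ls = [int(rng.integers(n_sp)) for _ in range(n_leaves)]
    if len(set(ls)) < min(n_sp, 2):
        ls[0] = 0
        ls[1] = n_sp - 1
    g = top.random_unrooted(range(n_leaves), rng)
    return s, g, ls


@pytest.fixture
def make_support():
    """Factory for small weighted topology supports on a given leaf count."""

    def _make(rng, n_topologies, n_leaves=4):
        seen = []
        while len(seen) < n_topologies:
            t = top.random_unrooted(range(n_leaves), rng)
            if t not in seen:
                seen.append(t)
        w = rng.dirichlet(np.ones(n_topologies))
        return seen, w

    return _make
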