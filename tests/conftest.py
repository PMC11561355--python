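import numpy as np
import pytest

import stygotrace as st
from stygotrace.dec import RangeStateSpace


@pytest.fixture(scope="session")
def cherry():
    """Two-tip tree, both branches 1 Ma."""
    return st.parse_newick("(x:1,y:1);")


@pytest.fixture(scope="session")
def balanced4():
    """Four-tip balanced ultrametric tree, root age 2 Ma."""
    return st.parse_newick("((a:1,b:1):1,(c:1,d:1):1);")


@pytest.fixture(scope="session")
def uni2():
    return st.AreaUniverse(("A", "B"))


@pytest.fixture(scope="session")
def uni3():
    return st.AreaUniverse(("A", "B", "C"))


@pytest.fixture(scope="session")
def space2(uni2):
    return RangeStateSpace(uni2, 2)


def random_small_tree(rng: np.random.Generator, max_tips: int = 4):
    """Random 2-4 tip ultrametric tree with random branch lengths."""
    n = int(rng.integers(2, max_tips + 1))
    tree, _ = st.simulate_bd_tree(1.0, 0.0, n, int(rng.integers(2**31 - 1)))
    return tree
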