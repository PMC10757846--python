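import pytest

import timegraft as tg


@pytest.fixture
def basic_tree() -> tg.TimeTree:
    """Three-tip chronogram with root age 2 and a cherry at age 1."""
    return tg.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def backbone_tree() -> tg.TimeTree:
    """The worked grafting backbone: ((A:5,C:5):5,E:10)."""
    return tg.read_newick("((Genus1_a:5,Genus1_c:5):5,Genus2_e:10);")


@pytest.fixture
def yule_tree() -> tg.TimeTree:
    return tg.simulate_bd_tree(tg.BDParams(lam=0.25, mu=0.0, n_tips=60, seed=42))


@pytest.fixture
def bd_tree() -> tg.TimeTree:
    return tg.simulate_bd_tree(tg.BDParams(lam=0.3, mu=0.1, n_tips=80, seed=7))
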