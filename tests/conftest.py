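import numpy as np
import pytest

from polymort import parse_newick, vcv
from polymort.demography import metrics_table
from polymort.pipeline import assemble
from polymort.synthetic import make_study_fixture


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1):1,C:2); with V = [[2,1,0],[1,2,0],[0,0,2]]."""
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree():
    return parse_newick("(" + ",".join(f"s{i}:1" for i in range(10)) + ");")


@pytest.fixture(scope="session")
def study():
    """Default 51-species synthetic comparative study plus its assembled dataset."""
    fx = make_study_fixture(n_species=51, seed=42)
    m = metrics_table(fx.life_tables)
    ds = assemble(m, fx.traits, fx.tree)
    return fx, m, ds


@pytest.fixture
def rng():
    return np.random.default_rng(7)
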