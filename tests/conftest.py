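import pytest

import phylocausal as pc


@pytest.fixture(scope="session")
def cherry():
    return pc.Phylogeny.from_newick("(A:1.0,B:1.0);")


@pytest.fixture(scope="session")
def three_tip():
    return pc.Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def balanced_four():
    return pc.Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def tree200():
    return pc.simulate_tree(200, seed=11)


@pytest.fixture(scope="session")
def model_c_dataset():
    """One aligned synthetic dataset generated under the model-c topology."""
    scen = pc.scenario("model_c", n_tips=250, seed=20)
    tree, traits, coords = pc.simulate_dataset(scen)
    return tree, traits, coords


@pytest.fixture(scope="session")
def null_dataset():
    scen = pc.scenario("null", n_tips=250, seed=21)
    tree, traits, coords = pc.simulate_dataset(scen)
    return tree, traits, coords
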