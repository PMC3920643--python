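import numpy as np
import pytest

from commphylo import read_newick
from commphylo.synthetic_data import ScenarioConfig, generate_scenario, simulate_tree


@pytest.fixture
def three_tip_tree():
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def six_tip_tree():
    # two clear clades of three, ultrametric, depth 10
    return read_newick("(((A:2,B:2):3,C:5):5,((D:1,E:1):4,F:5):5);")


@pytest.fixture(scope="session")
def yule100():
    """A 100-tip pure-birth tree reused by the simulation-heavy tests."""
    return simulate_tree(100, birth_rate=0.05, seed=2024)


@pytest.fixture(scope="session")
def scenario_small():
    """A compact end-to-end scenario (fast; richer one lives in acceptance tests)."""
    return generate_scenario(
        ScenarioConfig(
            n_species=80, n_plots=250, raster_dims=(20, 20), family_cut_age=45.0, seed=7
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(99)


def brute_force_patristic(tree):
    """Independent oracle: per-pair path walk summing branch lengths."""
    tips = [n for n in tree.iter_tips()]
    n = len(tips)
    D = np.zeros((n, n))

    def ancestors(node):
        out = []
        while node is not None:
            out.append(node)
            node = node.parent
        return out

    for i in range(n):
        for j in range(i + 1, n):
            ai = ancestors(tips[i])
            aj = ancestors(tips[j])
            shared = {id(a) for a in ai} & {id(a) for a in aj}
            d = 0.0
            for path in (ai, aj):
                for node in path:
                    if id(node) in shared:
                        break
                    d += node.parent.age - node.age
            D[i, j] = D[j, i] = d
    return D
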