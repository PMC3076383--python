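import numpy as np
import pytest

from skeinpath import fixtures as fx
from skeinpath import linkcore as lc
from skeinpath.fixtures import oracle_gauss_code
from skeinpath.homfly import homfly_of_gauss, propagate_weights
from skeinpath.skein import build_skein_tree


BATTERY_NAMES = [
    "3_1R",
    "3_1L",
    "4_1",
    "5_1R",
    "5_2R",
    "5_2L",
    "6_1R",
    "6_1L",
    "hopf+",
    "hopf-",
    "U",
    "unlink_2",
    "unlink_3",
]


def battery_link(name):
    if name == "3_1R":
        return fx.make_fixture(fx.FixtureSpec("torus_knot", 60, params=(2, 3)))
    if name == "3_1L":
        return lc.mirror_link(battery_link("3_1R"))
    if name == "4_1":
        return fx.make_fixture(fx.FixtureSpec("figure_eight", 100))
    if name == "5_1R":
        return fx.make_fixture(fx.FixtureSpec("torus_knot", 80, params=(2, 5)))
    if name == "5_2R":
        return fx.braid_link(*fx.BRAID_WORDS["5_2"])
    if name == "5_2L":
        return lc.mirror_link(battery_link("5_2R"))
    if name == "6_1R":
        return fx.braid_link(*fx.BRAID_WORDS["6_1"])
    if name == "6_1L":
        return lc.mirror_link(battery_link("6_1R"))
    if name in ("hopf+", "hopf-"):
        return fx.braid_link(*fx.BRAID_WORDS[name])
    if name == "U":
        return fx.make_fixture(fx.FixtureSpec("unlink", params=(1,)))
    if name.startswith("unlink_"):
        k = int(name.split("_")[1])
        return fx.make_fixture(fx.FixtureSpec("unlink", params=(k,)))
    raise KeyError(name)


@pytest.fixture(scope="session")
def battery():
    """name -> (link, oracle polynomial) for the shipped knot/link battery."""
    out = {}
    for name in BATTERY_NAMES:
        link = battery_link(name)
        oracle = homfly_of_gauss(oracle_gauss_code(_oracle_name(name)))
        out[name] = (link, oracle)
    return out


def _oracle_name(name):
    # mirrored braid entries: oracle codes carry L/R directly
    return name


@pytest.fixture(scope="session")
def pipeline_trees(battery):
    """(name, flip_index, strategy) -> (variant link, tree, polynomial)
    over all flips of every battery entry, for both selection strategies.

    Built once; reused by the oracle-equivalence, skein-identity and
    strategy-comparison acceptance tests.
    """
    out = {}
    for name, (link, oracle) in battery.items():
        for i, variant in enumerate(fx.flips(link)):
            for strategy in ("greedy", "fixed"):
                tree = build_skein_tree(variant, strategy=strategy, seed=7)
                poly = propagate_weights(tree)
                out[(name, i, strategy)] = (variant, tree, poly)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
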