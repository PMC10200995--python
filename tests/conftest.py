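import numpy as np
import pytest

from polyorigin.scenario import default_scenario
from polyorigin.treeio import GeneFamilyTree


@pytest.fixture(scope="session")
def truth():
    return default_scenario()


@pytest.fixture(scope="session")
def smap(truth):
    return truth.section_map()


@pytest.fixture
def make_tree():
    def _make(newick, tree_id="T1"):
        return GeneFamilyTree.from_newick(newick, tree_id)

    return _make


def random_rooted_newick(labels, rng):
    """Random rooted binary topology over the given leaf labels."""

    def build(items):
        if len(items) == 1:
            return items[0]
        k = int(rng.integers(1, len(items)))
        return f"({build(items[:k])},{build(items[k:])})"

    items = list(labels)
    items = [items[i] for i in rng.permutation(len(items))]
    return build(items) + ";"


@pytest.fixture
def random_tree_factory():
    return random_rooted_newick


def seeded_rng(seed):
    return np.random.default_rng(seed)
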