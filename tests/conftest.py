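import numpy as np
import pytest

from treecoclust import DifferentiationTree


@pytest.fixture
def seven_node_tree():
    """r -> (a, b); a -> (c, d); b -> (e, f).

    Small enough for brute-force checks of tree-respecting definitions.
    """
    return DifferentiationTree({
        "r": None, "a": "r", "b": "r",
        "c": "a", "d": "a", "e": "b", "f": "b",
    })


@pytest.fixture
def path_tree():
    """a -> b -> c."""
    return DifferentiationTree({"a": None, "b": "a", "c": "b"})


@pytest.fixture
def star_tree():
    """Root with five leaf children."""
    parent = {"root": None}
    parent.update({f"leaf{i}": "root" for i in range(5)})
    return DifferentiationTree(parent)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
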