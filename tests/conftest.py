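import numpy as np
import pytest

from morphomics.swc_io import RootedTree, SwcNode
from morphomics.synthetic_trees import TreeModelParams, generate_tree


@pytest.fixture
def toy_y_tree() -> RootedTree:
    """Soma at the origin, a stem node at radial 10, leaves at radial 14 and
    30 — all on the x axis, so every length is exact."""
    nodes = [
        SwcNode(1, 1, 0.0, 0.0, 0.0, 2.0, -1),
        SwcNode(2, 3, 10.0, 0.0, 0.0, 0.5, 1),
        SwcNode(3, 3, 14.0, 0.0, 0.0, 0.5, 2),
        SwcNode(4, 3, 30.0, 0.0, 0.0, 0.5, 2),
    ]
    return RootedTree(nodes, source_id="toy_y")


def make_random_tree(seed: int, max_leaves: int = 64) -> RootedTree:
    """A moderate random tree; regenerates at lower depth if too leafy."""
    for depth in (6, 5, 4):
        t = generate_tree(
            TreeModelParams(n_stems=3, branch_prob=0.5, max_depth=depth,
                            segment_length_mean=6.0, segment_length_sd=2.0,
                            radial_drift=0.7, seed=seed),
            source_id=f"rand_{seed}",
        )
        if len(t.leaves) <= max_leaves:
            return t
    return t


@pytest.fixture
def random_trees():
    return [make_random_tree(s) for s in range(30)]
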