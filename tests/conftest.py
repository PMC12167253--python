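import numpy as np
import pytest

from mtnav.demonstrations import run_oracle_episode
from mtnav.vasculature import (TreeParams, generate_straight_tree, generate_tree,
                               sample_target)


@pytest.fixture(scope="session")
def right_tree():
    return generate_tree(TreeParams(side="right"), seed=7)


@pytest.fixture(scope="session")
def left_tree():
    return generate_tree(TreeParams(side="left"), seed=8)


@pytest.fixture(scope="session")
def straight_tree():
    return generate_straight_tree(length=100.0, target_fraction=0.5)


@pytest.fixture(scope="session")
def oracle_batch():
    """40 oracle demonstrations over 10 trees (5 per side), shared across
    tests that audit demonstrator behavior."""
    demos = []
    for seed in range(10):
        side = "right" if seed % 2 == 0 else "left"
        tree = generate_tree(TreeParams(side=side), seed=seed)
        for k in range(2):
            target = sample_target(tree, seed=100 + k)
            for rep in range(2):
                demos.append(run_oracle_episode(tree, target, seed=10 * k + rep))
    return demos
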