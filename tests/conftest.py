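import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20190325)


def random_configuration(rng, k: int = 12, scale: float = 1.0) -> np.ndarray:
    """A non-degenerate random landmark configuration."""
    return rng.normal(0.0, scale, (k, 2))


def random_similarity(rng):
    """Random proper similarity transform (R, scale, translation)."""
    theta = rng.uniform(0, 2 * np.pi)
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    s = rng.uniform(0.2, 5.0)
    t = rng.uniform(-10, 10, 2)
    return R, s, t


def apply_similarity(coords, R, s, t):
    return coords @ R.T * s + t


def balanced_tree_newick(n_tips: int) -> str:
    """Fully balanced binary tree with tips t0..t{n-1} (n a power of 2)."""
    labels = [f"t{i}" for i in range(n_tips)]
    while len(labels) > 1:
        labels = [
            f"({labels[i]},{labels[i + 1]})" for i in range(0, len(labels), 2)
        ]
    return labels[0] + ";"


def random_tree_newick(rng, n_tips: int) -> str:
    """Random rooted binary topology built by successive joins."""
    nodes = [f"t{i}" for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    return nodes[0] + ";"
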