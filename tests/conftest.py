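import numpy as np
import pytest

from phylotastic.fixtures import GeneratorSpec, mammal_fixture, random_tree


@pytest.fixture(scope="session")
def mammal():
    """The packaged mammal demo tree and taxonomy table."""
    return mammal_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


def make_random_trees(n_trees, seed, max_tips=60, min_tips=2, **kwargs):
    """A deterministic batch of random trees with varied sizes."""
    rng = np.random.default_rng(seed)
    sizes = rng.integers(min_tips, max_tips + 1, size=n_trees)
    return [random_tree(GeneratorSpec(n_tips=int(n), seed=int(seed + i),
                                      **kwargs))
            for i, n in enumerate(sizes)]


def edit_distance_dp(a: str, b: str) -> int:
    """Independent Wagner–Fischer edit distance (the tests' oracle)."""
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1,
                         prev[j - 1] + (a[i - 1] != b[j - 1]))
        prev = cur
    return prev[n]
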