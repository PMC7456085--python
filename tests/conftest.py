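import numpy as np
import pytest

from binomialrf.forest import LEAF, ForestConfig, ForestStructure, TreeStructure


def make_tree(split_feature, left, right) -> TreeStructure:
    return TreeStructure(
        np.asarray(split_feature, dtype=np.int64),
        np.asarray(left, dtype=np.int64),
        np.asarray(right, dtype=np.int64),
    )


def stump(feature: int) -> TreeStructure:
    """Root split with two leaf children."""
    return make_tree([feature, LEAF, LEAF], [1, LEAF, LEAF], [2, LEAF, LEAF])


def single_leaf() -> TreeStructure:
    return make_tree([LEAF], [LEAF], [LEAF])


def chain(features) -> TreeStructure:
    """A left-descending chain splitting on the given features in order."""
    n = 2 * len(features) + 1
    split = [LEAF] * n
    left = [LEAF] * n
    right = [LEAF] * n
    node = 0
    for i, f in enumerate(features):
        split[node] = f
        left[node] = node + 1  # next internal node (or final leaf)
        right[node] = 2 * len(features) - i  # private leaf
        node += 1
    return make_tree(split, left, right)


def full_depth2(root: int, left_feat: int, right_feat: int) -> TreeStructure:
    """Root plus two internal children, four leaves."""
    split = [root, left_feat, right_feat, LEAF, LEAF, LEAF, LEAF]
    left = [1, 3, 5, LEAF, LEAF, LEAF, LEAF]
    right = [2, 4, 6, LEAF, LEAF, LEAF, LEAF]
    return make_tree(split, left, right)


def forest_of(trees, P, m=None, n=63, N=100, **config_kwargs) -> ForestStructure:
    """Wrap hand-built trees in a ForestStructure with stated sampling params."""
    if m is None:
        m = max(1, round(P / 3))
    config = ForestConfig(ntree=len(trees), **config_kwargs)
    return ForestStructure(
        trees=list(trees),
        config=config,
        n_features=P,
        feature_names=[f"f{j}" for j in range(P)],
        m=m,
        n=n,
        n_samples=N,
    )


@pytest.fixture
def trained_forest():
    """A small seeded-signal forest reused across tests (trained once)."""
    from binomialrf import ForestConfig, SimulationConfig, simulate_logistic, train_forest

    cfg = SimulationConfig(
        P=50, n_seeded=3, effect_size=2.0, N=80, seed=7,
        forest=ForestConfig(ntree=150, seed=7),
    )
    dataset, truth = simulate_logistic(cfg)
    return train_forest(dataset, cfg.forest), dataset, truth
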