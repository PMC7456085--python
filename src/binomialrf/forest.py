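"""Random-forest training and split-structure access.

The statistical machinery only needs each tree's *split structure*: which
feature the root splits on, and the feature sequences along root decision
paths.  Growing the trees themselves (impurity maximisation, prediction) is
delegated to scikit-learn; this module adapts fitted trees into plain arrays
so that any binary-tree learner exposing (split feature, children, leaf
flags) per node can be plugged in, and forests can round-trip through JSON
for fixtures.

Two sampling modes are supported per tree:

``subsample``
    each tree is fitted on ``n`` distinct cases drawn without replacement
    (default ``n = ceil(0.632 * N)``); implemented as one seeded
    ``DecisionTreeClassifier`` fit per row subset.
``bootstrap``
    scikit-learn's own ``RandomForestClassifier`` with ``N`` draws with
    replacement.

Features are subsampled per split (``max_features = m``); the draw at the
root is the event the selection test models.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from .errors import ValidationError

__all__ = [
    "ForestConfig",
    "TreeStructure",
    "ForestStructure",
    "train_forest",
    "root_feature",
    "enumerate_root_paths",
]

LEAF = -1  # sentinel in split_feature / child arrays at leaves


@dataclass(frozen=True)
class ForestConfig:
    """Forest-growing parameters.

    ``feature_fraction`` is the proportion of features drawn at each split,
    realized as ``m = max(1, round(fraction * P))``; 1/3 is the customary
    classification default.  ``sample_count`` is the number of cases each
    tree sees (``None`` = ceil(0.632 * N) in subsample mode, N in bootstrap
    mode).
    """

    ntree: int = 500
    feature_fraction: float = 1.0 / 3.0
    sample_count: Optional[int] = None
    sampling_mode: str = "subsample"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ValidationError(f"ntree must be >= 1, got {self.ntree}")
        if not 0.0 < self.feature_fraction <= 1.0:
            raise ValidationError(
                f"feature_fraction must lie in (0, 1], got {self.feature_fraction}"
            )
        if self.sampling_mode not in ("subsample", "bootstrap"):
            raise ValidationError(
                f"sampling_mode must be 'subsample' or 'bootstrap', got {self.sampling_mode!r}"
            )
        if self.sample_count is not None and self.sample_count < 1:
            raise ValidationError("sample_count must be >= 1")

    def features_per_split(self, n_features: int) -> int:
        m = max(1, round(self.feature_fraction * n_features))
        return min(m, n_features)

    def cases_per_tree(self, n_samples: int) -> int:
        if self.sample_count is not None:
            n = self.sample_count
            if self.sampling_mode == "subsample" and n > n_samples:
                raise ValidationError(
                    f"sample_count {n} exceeds available cases {n_samples} for subsampling"
                )
            return n
        if self.sampling_mode == "bootstrap":
            return n_samples
        return math.ceil(0.632 * n_samples)


@dataclass(frozen=True)
class TreeStructure:
    """One binary split tree as parallel per-node arrays (root = node 0)."""

    split_feature: np.ndarray  # feature index at internal nodes, LEAF at leaves
    left_child: np.ndarray
    right_child: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.split_feature)
        if n == 0 or len(self.left_child) != n or len(self.right_child) != n:
            raise ValidationError("tree arrays must be non-empty and equal length")
        leaves = self.left_child == LEAF
        if not np.array_equal(leaves, self.right_child == LEAF):
            raise ValidationError("leaves must lack both children")
        if np.any(self.split_feature[leaves] != LEAF):
            raise ValidationError("leaf nodes must not carry a split feature")
        if np.any(self.split_feature[~leaves] < 0):
            raise ValidationError("internal nodes must carry a split feature")
        kids = np.concatenate([self.left_child[~leaves], self.right_child[~leaves]])
        if kids.size and (kids.min() < 1 or kids.max() >= n):
            raise ValidationError("child indices out of range")

    @property
    def n_nodes(self) -> int:
        return len(self.split_feature)

    @property
    def is_leaf(self) -> np.ndarray:
        return self.left_child == LEAF

    @classmethod
    def from_sklearn(cls, sk_tree) -> "TreeStructure":
        t = sk_tree.tree_
        feat = np.where(t.children_left == -1, LEAF, t.feature).astype(np.int64)
        left = np.where(t.children_left == -1, LEAF, t.children_left).astype(np.int64)
        right = np.where(t.children_right == -1, LEAF, t.children_right).astype(np.int64)
        return cls(feat, left, right)

    def to_lists(self) -> dict:
        return {
            "split_feature": self.split_feature.tolist(),
            "left_child": self.left_child.tolist(),
            "right_child": self.right_child.tolist(),
        }

    @classmethod
    def from_lists(cls, d: dict) -> "TreeStructure":
        return cls(
            np.asarray(d["split_feature"], dtype=np.int64),
            np.asarray(d["left_child"], dtype=np.int64),
            np.asarray(d["right_child"], dtype=np.int64),
        )


@dataclass
class ForestStructure:
    """A trained ensemble reduced to its split trees plus sampling parameters."""

    trees: list
    config: ForestConfig
    n_features: int
    feature_names: list
    m: int  # realized features sampled per split
    n: int  # realized cases per tree
    n_samples: int  # N, total cases in the training data

    def __post_init__(self) -> None:
        if len(self.feature_names) != self.n_features:
            raise ValidationError("feature_names length must equal n_features")
        for t in self.trees:
            internal = t.split_feature[~t.is_leaf]
            if internal.size and internal.max() >= self.n_features:
                raise ValidationError("split feature index exceeds feature count")

    @property
    def V(self) -> int:
        return len(self.trees)

    @property
    def n_degenerate(self) -> int:
        """Trees that are a single leaf (no root split)."""
        return sum(int(t.is_leaf[0]) for t in self.trees)

    def __iter__(self) -> Iterator[TreeStructure]:
        return iter(self.trees)

    def default_rho(self) -> float:
        """Tree-to-tree co-dependency as the case-overlap fraction n / N."""
        return self.n / self.n_samples

    def to_json(self, path=None) -> str:
        payload = {
            "config": {
                "ntree": self.config.ntree,
                "feature_fraction": self.config.feature_fraction,
                "sample_count": self.config.sample_count,
                "sampling_mode": self.config.sampling_mode,
                "seed": self.config.seed,
            },
            "n_features": self.n_features,
            "feature_names": list(self.feature_names),
            "m": self.m,
            "n": self.n,
            "n_samples": self.n_samples,
            "trees": [t.to_lists() for t in self.trees],
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source: str) -> "ForestStructure":
        if "\n" not in source and not source.lstrip().startswith("{"):
            with open(source) as fh:
                source = fh.read()
        d = json.loads(source)
        return cls(
            trees=[TreeStructure.from_lists(t) for t in d["trees"]],
            config=ForestConfig(**d["config"]),
            n_features=d["n_features"],
            feature_names=d["feature_names"],
            m=d["m"],
            n=d["n"],
            n_samples=d["n_samples"],
        )


def _check_training_data(X: np.ndarray, y: np.ndarray) -> None:
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValidationError("X must be a 2-D matrix with >= 2 rows and >= 1 column")
    if len(y) != X.shape[0]:
        raise ValidationError("y length must match the number of rows of X")
    if len(np.unique(y)) != 2:
        raise ValidationError("y must contain exactly two classes")


def train_forest(dataset, config: ForestConfig = ForestConfig()) -> ForestStructure:
    """Grow ``config.ntree`` trees and return their split structures.

    Deterministic given ``config.seed``: the per-tree row subsets and the
    per-split feature draws both derive from it.
    """
    X = np.asarray(dataset.X, dtype=float)
    y = np.asarray(dataset.y)
    _check_training_data(X, y)
    N, P = X.shape
    m = config.features_per_split(P)
    n = config.cases_per_tree(N)

    if config.sampling_mode == "bootstrap":
        rf = RandomForestClassifier(
            n_estimators=config.ntree,
            max_features=m,
            bootstrap=True,
            max_samples=None if n == N else n,
            random_state=config.seed,
            n_jobs=1,
        )
        rf.fit(X, y)
        trees = [TreeStructure.from_sklearn(est) for est in rf.estimators_]
    else:
        rng = np.random.default_rng(config.seed)
        trees = []
        for _ in range(config.ntree):
            rows = rng.choice(N, size=n, replace=False)
            tree_seed = int(rng.integers(0, 2**31 - 1))
            clf = DecisionTreeClassifier(max_features=m, random_state=tree_seed)
            clf.fit(X[rows], y[rows])
            trees.append(TreeStructure.from_sklearn(clf))

    names = list(getattr(dataset, "feature_names", None) or [f"f{j}" for j in range(P)])
    return ForestStructure(
        trees=trees,
        config=config,
        n_features=P,
        feature_names=names,
        m=m,
        n=n,
        n_samples=N,
    )


def root_feature(tree: TreeStructure) -> Optional[int]:
    """Feature index at the root split, or ``None`` for a single-leaf tree."""
    if tree.is_leaf[0]:
        return None
    return int(tree.split_feature[0])


def enumerate_root_paths(tree: TreeStructure, K: int) -> set:
    """All ordered feature tuples along root chains of exactly K internal nodes.

    Each tuple is the split-feature sequence from the root (depth 0) through
    depth ``K-1``; tuples with a repeated feature are discarded because a
    feature interacting with itself is just a main effect.  Returns the empty
    set when the tree has no chain of ``K`` internal nodes.
    """
    if K < 2:
        raise ValidationError(f"K must be >= 2, got {K}")
    out: set = set()
    if tree.is_leaf[0]:
        return out
    stack = [(0, ())]
    while stack:
        node, feats = stack.pop()
        if tree.is_leaf[node]:
            continue
        feats = feats + (int(tree.split_feature[node]),)
        if len(feats) == K:
            if len(set(feats)) == K:
                out.add(feats)
            continue
        stack.append((int(tree.left_child[node]), feats))
        stack.append((int(tree.right_child[node]), feats))
    return out
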