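"""Main-effects selection test.

Under the null hypothesis that no feature is informative, every feature is
equally likely to win the root split of a tree, with probability
``p_root = 1/P``.  The observed root-split frequency ``F_j`` of feature ``j``
across ``V`` trees is therefore compared against a correlated binomial
``CorrBinom(V, 1/P, rho)`` null, one-sidedly (only over-selection counts as a
discovery), and the resulting p-values are adjusted by Benjamini–Yekutieli,
which is valid under the arbitrary dependence induced by the shared-root
constraint ``sum_j F_j = V``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import corrbinom
from .corrbinom import CorrBinomSpec
from .errors import ValidationError
from .forest import ForestConfig, ForestStructure, root_feature
from .multiplicity import adjust_pvalues

__all__ = [
    "Dataset",
    "count_root_frequencies",
    "p_root",
    "main_effects_test",
    "adjust_by",
    "cv_feature_fraction",
    "refit_and_score",
]

RESULT_COLUMNS = [
    "feature",
    "name",
    "frequency",
    "null_prob",
    "pvalue",
    "adj_pvalue",
    "significant",
]


@dataclass
class Dataset:
    """Numeric sample-by-feature matrix with a binary outcome.

    ``X`` is N x P (e.g. normalized expression, samples in rows); ``y`` holds
    the two class labels encoded as 0/1.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list = field(default=None)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValidationError("X must be a 2-D samples-by-features matrix")
        if self.X.shape[0] < 2 or self.X.shape[1] < 1:
            raise ValidationError("need at least 2 samples and 1 feature")
        if np.isnan(self.X).any():
            raise ValidationError("X contains missing values")
        if len(y) != self.X.shape[0]:
            raise ValidationError("y length must equal the number of samples")
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValidationError(
                f"y must contain exactly two classes, found {len(classes)}"
            )
        self.y = (y == classes[1]).astype(np.int64)
        if self.feature_names is None:
            self.feature_names = [f"f{j}" for j in range(self.X.shape[1])]
        if len(self.feature_names) != self.X.shape[1]:
            raise ValidationError("feature_names length must equal feature count")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValidationError("feature names must be unique")

    @property
    def N(self) -> int:
        return self.X.shape[0]

    @property
    def P(self) -> int:
        return self.X.shape[1]


def count_root_frequencies(forest: ForestStructure) -> np.ndarray:
    """Root-split frequency F_j per feature; never-selected features get 0.

    ``sum_j F_j`` equals the number of trees with a root split (degenerate
    single-leaf trees contribute nothing).
    """
    counts = np.zeros(forest.n_features, dtype=np.int64)
    for tree in forest:
        j = root_feature(tree)
        if j is not None:
            counts[j] += 1
    return counts


def p_root(P: int, m: int) -> float:
    """Null probability that a given feature wins the root split.

    Evaluated through the sequential-sampling product: the chance that the
    feature is *not* among the ``m`` candidates drawn (without replacement)
    is the telescoping product ``prod_{g=1..m} (P-g)/(P-g+1) = (P-m)/P``;
    conditional on being drawn it wins with probability ``1/m`` under the
    null, so ``p_root = (1/m) * (1 - (P-m)/P) = 1/P``, uniform over features.
    The product form is evaluated and checked against ``1/P`` at run time.
    """
    if m < 1 or m > P:
        raise ValidationError(f"need 1 <= m <= P, got m={m}, P={P}")
    prod = 1.0
    for g in range(1, m + 1):
        prod *= (P - g) / (P - g + 1)
    val = (1.0 / m) * (1.0 - prod)
    if not math.isclose(val, 1.0 / P, rel_tol=1e-9):
        raise AssertionError(
            f"telescoping evaluation {val!r} disagrees with 1/P for P={P}, m={m}"
        )
    return val


def adjust_by(
    pvalues: Sequence[float],
    method: str = "BY",
    family_size: Optional[int] = None,
) -> np.ndarray:
    """Multiplicity-adjusted p-values in the input order (default BY)."""
    return adjust_pvalues(pvalues, method=method, family_size=family_size)


def _resolve_rho(forest: ForestStructure, rho) -> float:
    if rho == "auto" or rho is None:
        return forest.default_rho()
    rho = float(rho)
    if not 0.0 <= rho < 1.0:
        raise ValidationError(f"rho must lie in [0, 1), got {rho}")
    return rho


def main_effects_test(
    forest: ForestStructure,
    alpha: float = 0.05,
    rho: Union[str, float] = "auto",
    fdr_method: str = "BY",
    model: str = "witt",
) -> pd.DataFrame:
    """Test every feature's root-split frequency against the correlated null.

    Returns one row per feature (all ``P`` hypotheses enter the family) with
    columns ``feature, name, frequency, null_prob, pvalue, adj_pvalue,
    significant``, sorted by p-value, then frequency (descending), then
    feature index.
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    freq = count_root_frequencies(forest)
    V_eff = forest.V - forest.n_degenerate
    if V_eff < 1:
        raise ValidationError("forest has no tree with a root split")
    p0 = p_root(forest.n_features, forest.m)
    spec = corrbinom.validate_spec(
        CorrBinomSpec(V_eff, p0, _resolve_rho(forest, rho), model=model)
    )
    tail = corrbinom.upper_tail_vector(spec)
    pvals = tail[freq]
    adj = adjust_by(pvals, method=fdr_method)
    out = pd.DataFrame(
        {
            "feature": np.arange(forest.n_features),
            "name": forest.feature_names,
            "frequency": freq,
            "null_prob": p0,
            "pvalue": pvals,
            "adj_pvalue": adj,
            "significant": adj <= alpha,
        }
    )
    out = out.sort_values(
        by=["pvalue", "frequency", "feature"],
        ascending=[True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return out


def cv_feature_fraction(
    dataset: Dataset,
    folds: int,
    config: ForestConfig = ForestConfig(),
) -> float:
    """Pick the per-split feature-sampling proportion by cross-validation.

    Evaluates the equally spaced grid ``{i/(folds+1) : i = 1..folds}`` by
    stratified ``folds``-fold cross-validated misclassification error of a
    forest grown at each proportion, returning the proportion with the lowest
    mean error (ties go to the smallest proportion).
    """
    if folds < 2:
        raise ValidationError(f"folds must be >= 2, got {folds}")
    counts = np.bincount(dataset.y)
    if counts.min() < folds:
        raise ValidationError(
            f"too few samples in the minority class ({counts.min()}) for {folds} folds"
        )
    grid = [i / (folds + 1) for i in range(1, folds + 1)]
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=config.seed)
    splits = list(splitter.split(dataset.X, dataset.y))
    errors = []
    for frac in grid:
        m = max(1, round(frac * dataset.P))
        fold_err = []
        for train_idx, test_idx in splits:
            clf = RandomForestClassifier(
                n_estimators=config.ntree,
                max_features=min(m, dataset.P),
                random_state=config.seed,
                n_jobs=1,
            )
            clf.fit(dataset.X[train_idx], dataset.y[train_idx])
            pred = clf.predict(dataset.X[test_idx])
            fold_err.append(float(np.mean(pred != dataset.y[test_idx])))
        errors.append(float(np.mean(fold_err)))
    best = int(np.argmin(errors))  # argmin returns the first (smallest) on ties
    return grid[best]


def refit_and_score(
    dataset: Dataset,
    selected: Sequence[int],
    config: ForestConfig = ForestConfig(),
    holdout: float = 0.25,
) -> float:
    """Held-out misclassification of a forest refitted on selected features."""
    selected = sorted(set(int(j) for j in selected))
    if not selected:
        raise ValidationError("selected feature set is empty")
    if selected[0] < 0 or selected[-1] >= dataset.P:
        raise ValidationError("selected feature index out of range")
    X = dataset.X[:, selected]
    X_tr, X_te, y_tr, y_te = train_test_split(
        X,
        dataset.y,
        test_size=holdout,
        stratify=dataset.y,
        random_state=config.seed,
    )
    clf = RandomForestClassifier(
        n_estimators=config.ntree,
        max_features=config.features_per_split(len(selected)),
        random_state=config.seed,
        n_jobs=1,
    )
    clf.fit(X_tr, y_tr)
    return float(np.mean(clf.predict(X_te) != y_te))
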