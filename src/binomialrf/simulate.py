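"""Synthetic data generator and evaluation bench.

Datasets mimic binary-outcome expression studies through a logistic model:
``X`` is N x P i.i.d. standard normal ("normalized expression" of a
synthetic genome), a sparse coefficient vector seeds the informative
features, and ``y ~ Bernoulli(expit(X @ beta))``.  Three scenarios:

``main_effects``
    the first ``n_seeded`` features carry coefficient ``effect_size``.
``pure_noise``
    no coefficients at all; ``y ~ Bernoulli(1/2)`` independent of ``X``, so
    every selection is a false positive and the selected fraction is an
    empirical type-I error.
``interactions``
    4 main effects plus all 6 pairwise products of them (standardized so
    mains and products enter on a comparable scale) in a 30-feature genome.

Selections are scored by model size, precision, recall, held-out
misclassification, and the pure-noise selection rate (selected noise
features over the genome size).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from .core import Dataset
from .errors import ValidationError
from .forest import ForestConfig

__all__ = [
    "SimulationConfig",
    "MetricsReport",
    "SimulationTruth",
    "simulate_logistic",
    "simulate_null",
    "simulate_interactions",
    "evaluate_selection",
    "run_benchmark",
]

SCENARIOS = ("main_effects", "pure_noise", "interactions")


@dataclass(frozen=True)
class SimulationConfig:
    """One simulation condition.

    Defaults follow the benchmark grid: genome sizes 100-2000, 5-100 seeded
    features, forests of 500 or 1000 trees with a third of the features per
    split.  The generative distribution of ``X`` and the coefficient
    magnitude are free choices of the bench (standard normal expression,
    ``effect_size`` 2.0, N = 100 subjects) and are stated, not fitted.
    """

    P: int = 100
    n_seeded: int = 5
    effect_size: float = 2.0
    N: int = 100
    forest: ForestConfig = field(default_factory=ForestConfig)
    scenario: str = "main_effects"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValidationError(f"scenario must be one of {SCENARIOS}")
        if self.P < 1 or self.N < 2:
            raise ValidationError("need P >= 1 and N >= 2")
        if not 0 <= self.n_seeded <= self.P:
            raise ValidationError("n_seeded must lie in [0, P]")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be >= 0")
        if self.scenario == "pure_noise" and self.effect_size != 0:
            raise ValidationError("pure_noise requires effect_size = 0")
        if self.scenario == "interactions" and self.P < 30:
            raise ValidationError("interaction scenario needs P >= 30")


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth of a simulated dataset: seeded mains and seeded pairs."""

    mains: frozenset
    pairs: frozenset = frozenset()


@dataclass
class MetricsReport:
    """The five selection-accuracy metrics for one replicate."""

    model_size: int
    precision: float
    recall: float
    test_error: float
    noise_rate: float

    def to_dict(self) -> dict:
        return {
            "model_size": self.model_size,
            "precision": self.precision,
            "recall": self.recall,
            "test_error": self.test_error,
            "noise_rate": self.noise_rate,
        }


def _draw_labels(rng: np.random.Generator, eta: np.ndarray) -> np.ndarray:
    y = rng.binomial(1, expit(eta))
    if y.min() == y.max():  # degenerate draw; flip one label to keep two classes
        y[rng.integers(0, len(y))] ^= 1
    return y


def simulate_logistic(config: SimulationConfig) -> Tuple[Dataset, SimulationTruth]:
    """Main-effects logistic draw; reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    X = rng.standard_normal((config.N, config.P))
    beta = np.zeros(config.P)
    beta[: config.n_seeded] = config.effect_size
    y = _draw_labels(rng, X @ beta)
    names = [f"g{j}" for j in range(config.P)]
    truth = SimulationTruth(mains=frozenset(range(config.n_seeded)))
    return Dataset(X, y, names), truth


def simulate_null(config: SimulationConfig) -> Tuple[Dataset, SimulationTruth]:
    """Pure-noise draw: outcome independent of every feature (empty truth)."""
    cfg = replace(config, scenario="pure_noise", n_seeded=0, effect_size=0.0)
    dataset, _ = simulate_logistic(cfg)
    return dataset, SimulationTruth(mains=frozenset())


def simulate_interactions(config: SimulationConfig) -> Tuple[Dataset, SimulationTruth]:
    """Four seeded mains and all six of their pairwise product interactions.

    Product columns are standardized before entering the linear predictor so
    the interaction signal is on the same scale as the mains.  The explicit
    design a column-multiplying method would need at P = 30 has
    ``30 + C(30, 2) = 465`` columns; the tree screen keeps 30.
    """
    n_mains = 4
    rng = np.random.default_rng(config.seed)
    X = rng.standard_normal((config.N, config.P))
    eta = config.effect_size * X[:, :n_mains].sum(axis=1)
    pairs = list(combinations(range(n_mains), 2))
    for i, j in pairs:
        z = X[:, i] * X[:, j]
        z = (z - z.mean()) / z.std()
        eta = eta + config.effect_size * z
    y = _draw_labels(rng, eta)
    names = [f"g{j}" for j in range(config.P)]
    truth = SimulationTruth(
        mains=frozenset(range(n_mains)),
        pairs=frozenset(tuple(sorted(p)) for p in pairs),
    )
    return Dataset(X, y, names), truth


def simulate(config: SimulationConfig) -> Tuple[Dataset, SimulationTruth]:
    """Dispatch on ``config.scenario``."""
    if config.scenario == "pure_noise":
        return simulate_null(config)
    if config.scenario == "interactions":
        return simulate_interactions(config)
    return simulate_logistic(config)


def evaluate_selection(
    selected: Set[int],
    truth: Set[int],
    total_features: int,
    predictions: Optional[np.ndarray] = None,
    labels: Optional[np.ndarray] = None,
) -> MetricsReport:
    """Score a selected feature set against the seeded truth.

    Precision is 1.0 when both sets are empty and NaN when nothing was
    selected but truth exists; test error is the held-out misclassification
    fraction (NaN when no predictions are supplied); noise rate is the
    selected-noise count over the genome size.
    """
    selected = set(int(j) for j in selected)
    truth = set(int(j) for j in truth)
    if selected and (min(selected) < 0 or max(selected) >= total_features):
        raise ValidationError("selected index outside the feature range")
    if truth and (min(truth) < 0 or max(truth) >= total_features):
        raise ValidationError("truth index outside the feature range")
    tp = len(selected & truth)
    fp = len(selected - truth)
    fn = len(truth - selected)
    if selected:
        precision = tp / (tp + fp)
    else:
        precision = 1.0 if not truth else float("nan")
    recall = tp / (tp + fn) if truth else 1.0
    if predictions is not None:
        if labels is None or len(predictions) != len(labels):
            raise ValidationError("predictions and labels must align")
        test_error = float(np.mean(np.asarray(predictions) != np.asarray(labels)))
    else:
        test_error = float("nan")
    noise_rate = fp / total_features
    return MetricsReport(
        model_size=len(selected),
        precision=precision,
        recall=recall,
        test_error=test_error,
        noise_rate=noise_rate,
    )


def run_replicate(
    config: SimulationConfig,
    alpha: float = 0.05,
    rho="auto",
    fdr_method: str = "BY",
    refit: bool = False,
) -> MetricsReport:
    """Simulate one dataset, run the selection test, and score it."""
    from .core import main_effects_test, refit_and_score
    from .forest import train_forest

    dataset, truth = simulate(config)
    forest = train_forest(dataset, config.forest)
    results = main_effects_test(forest, alpha=alpha, rho=rho, fdr_method=fdr_method)
    selected = set(results.loc[results["significant"], "feature"].tolist())
    report = evaluate_selection(selected, set(truth.mains), config.P)
    if refit and selected:
        report.test_error = refit_and_score(dataset, selected, config.forest)
    return report


def run_benchmark(
    grid: Sequence[SimulationConfig],
    replicates: int = 20,
    alpha: float = 0.05,
    rho="auto",
    fdr_method: str = "BY",
    refit: bool = False,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Mean (sd) of every metric per grid condition, plus raw records.

    Replicate ``r`` of a condition reuses the condition's seed offset by
    ``r`` so the whole bench is reproducible from the per-condition seeds.
    """
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    records: List[dict] = []
    for cfg in grid:
        for r in range(replicates):
            rep_cfg = replace(
                cfg,
                seed=cfg.seed + r,
                forest=replace(cfg.forest, seed=cfg.forest.seed + r),
            )
            report = run_replicate(
                rep_cfg, alpha=alpha, rho=rho, fdr_method=fdr_method, refit=refit
            )
            records.append(
                {
                    "scenario": cfg.scenario,
                    "P": cfg.P,
                    "n_seeded": cfg.n_seeded,
                    "effect_size": cfg.effect_size,
                    "N": cfg.N,
                    "ntree": cfg.forest.ntree,
                    "replicate": r,
                    **report.to_dict(),
                }
            )
    raw = pd.DataFrame.from_records(records)
    keys = ["scenario", "P", "n_seeded", "effect_size", "N", "ntree"]
    metrics = ["model_size", "precision", "recall", "test_error", "noise_rate"]
    summary = raw.groupby(keys)[metrics].agg(["mean", "std"])
    summary.columns = [f"{m}_{s}" for m, s in summary.columns]
    std_cols = [c for c in summary.columns if c.endswith("_std")]
    summary[std_cols] = summary[std_cols].fillna(0.0)  # single replicate: sd = 0
    return summary.reset_index(), raw
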