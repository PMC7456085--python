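"""K-way interaction screening from root decision paths.

Binary trees encode interactions structurally: a chain of K sequential
splits from the root conditions each later split on all earlier ones, so the
feature K-tuples appearing on root decision paths are the candidate K-way
interactions (strong heredity holds by construction).  Each tree either
contains a given tuple on some root path or it does not, giving a V-trial
presence count that is tested against a correlated binomial null with a
much smaller success probability than a main effect's.

Null probabilities (sequential sampling without replacement, with a
``1/2^(K-1)`` normalizer for the number of terminal chains a K-way
interaction can occupy in a binary tree):

    p_2way = 1/2 * 1/P * 1/(P-1)
    p_Kway = 1/2^(K-1) * prod_{k=1..K} 1/(P-k)        (K >= 3)

The two formulas deliberately disagree at K = 2 (the K >= 3 form starts its
denominators at P-1 rather than P); the 2-way form governs pairs here.  Note
the normalizer *lowers* the null probability, i.e. it is the permissive
rather than the conservative direction; it is kept as specified upstream and
flagged in the docs.
"""

from __future__ import annotations

from collections import Counter
from typing import Dict, Optional, Tuple, Union

import networkx as nx
import numpy as np
import pandas as pd

from . import corrbinom
from .corrbinom import CorrBinomSpec
from .errors import ValidationError
from .forest import ForestStructure, enumerate_root_paths
from .multiplicity import adjust_pvalues

__all__ = [
    "p_2way",
    "p_kway",
    "count_path_frequencies",
    "interaction_test",
    "interaction_network",
    "interaction_design_size",
]


def _bracket(P: int, m: int) -> float:
    """(1/m) * (1 - prod_{g=1..m} (P-g)/(P-g+1)) for one sequential draw."""
    m = min(m, P)  # a bracket over fewer remaining features saturates at m = P
    prod = 1.0
    for g in range(1, m + 1):
        prod *= (P - g) / (P - g + 1)
    return (1.0 / m) * (1.0 - prod)


def p_2way(P: int, m: int) -> float:
    """Null probability of a given unordered feature pair on a 2-deep root path."""
    if P < 2:
        raise ValidationError(f"need P >= 2 features for pairs, got {P}")
    if m < 1 or m > P - 1:
        raise ValidationError(f"need 1 <= m <= P-1, got m={m}")
    val = 0.5 * _bracket(P, m) * _bracket(P - 1, m)
    expected = 0.5 / (P * (P - 1))
    assert abs(val - expected) <= 1e-12 * expected
    return val


def p_kway(P: int, m: int, K: int) -> float:
    """Null probability of a K-tuple on a root path (K >= 3; K = 2 uses p_2way).

    A conservative bound under sequential without-replacement sampling:
    ``(1/2^(K-1)) * prod_{k=1..K} 1/(P-k)``.
    """
    if K == 2:
        return p_2way(P, m)
    if K < 2:
        raise ValidationError(f"K must be >= 2, got {K}")
    if P <= K:
        raise ValidationError(f"need P > K, got P={P}, K={K}")
    val = 0.5 ** (K - 1)
    for k in range(1, K + 1):
        val *= _bracket(P - k, m)
    return val


def count_path_frequencies(forest: ForestStructure, K: int = 2) -> Dict[tuple, int]:
    """Per-tree presence counts of sorted K-tuples on root decision paths.

    Each distinct tuple contributes at most once per tree (a Bernoulli
    presence indicator per trial), however many paths realize it.
    """
    counts: Counter = Counter()
    for tree in forest:
        tuples = {tuple(sorted(path)) for path in enumerate_root_paths(tree, K)}
        counts.update(tuples)
    return dict(counts)


def interaction_test(
    forest: ForestStructure,
    K: int = 2,
    alpha: float = 0.05,
    rho: Union[str, float] = "auto",
    fdr_method: str = "BY",
    model: str = "witt",
    universe: str = "observed",
    ordered: bool = False,
) -> pd.DataFrame:
    """Test observed K-tuples against the correlated binomial path null.

    ``universe="observed"`` (default) adjusts across the tuples actually seen
    in the forest; ``universe="full"`` adjusts against the declared family of
    all C(P, K) tuples (unobserved members are implicit p = 1).
    ``ordered=True`` keeps path order instead of canonical sorted tuples, for
    diagnostics.  ``K=1`` is a main effect and is routed accordingly.
    """
    if K == 1:
        from .core import main_effects_test

        return main_effects_test(forest, alpha=alpha, rho=rho, fdr_method=fdr_method, model=model)
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    if universe not in ("observed", "full"):
        raise ValidationError("universe must be 'observed' or 'full'")

    if ordered:
        counts: Counter = Counter()
        for tree in forest:
            counts.update(set(enumerate_root_paths(tree, K)))
        counts = dict(counts)
    else:
        counts = count_path_frequencies(forest, K)

    p_null = p_kway(forest.n_features, forest.m, K)
    columns = ["features", "names", "frequency", "null_prob", "pvalue", "adj_pvalue", "significant"]
    if not counts:
        return pd.DataFrame(columns=columns)

    from .core import _resolve_rho  # shared rho resolution

    spec = corrbinom.validate_spec(
        CorrBinomSpec(forest.V - forest.n_degenerate, p_null, _resolve_rho(forest, rho), model=model)
    )
    tail = corrbinom.upper_tail_vector(spec)
    tuples = sorted(counts)
    freq = np.array([counts[t] for t in tuples], dtype=np.int64)
    pvals = tail[freq]
    family = None
    if universe == "full":
        from math import comb

        family = comb(forest.n_features, K)
    adj = adjust_pvalues(pvals, method=fdr_method, family_size=family)
    out = pd.DataFrame(
        {
            "features": tuples,
            "names": [tuple(forest.feature_names[j] for j in t) for t in tuples],
            "frequency": freq,
            "null_prob": p_null,
            "pvalue": pvals,
            "adj_pvalue": adj,
            "significant": adj <= alpha,
        }
    )
    out = out.sort_values(
        by=["pvalue", "frequency", "features"],
        ascending=[True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return out


def interaction_network(
    results: pd.DataFrame,
    threshold: Optional[float] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Edge list and node-degree table of significant pairwise interactions.

    Edges are the pairs flagged significant (or with ``adj_pvalue <=
    threshold`` when given); the degree table ranks features by how many
    significant interactions they join, surfacing "super-interactors".
    Only defined for K = 2 results.
    """
    if len(results) and any(len(t) != 2 for t in results["features"]):
        raise ValidationError("interaction_network expects pairwise (K=2) results")
    if threshold is None:
        keep = results[results["significant"]] if len(results) else results
    else:
        keep = results[results["adj_pvalue"] <= threshold]
    graph = nx.Graph()
    edges = pd.DataFrame(
        {
            "source": [t[0] for t in keep["features"]],
            "target": [t[1] for t in keep["features"]],
            "source_name": [n[0] for n in keep["names"]],
            "target_name": [n[1] for n in keep["names"]],
            "frequency": np.asarray(keep["frequency"], dtype=np.int64),
            "adj_pvalue": np.asarray(keep["adj_pvalue"], dtype=float),
        }
    )
    graph.add_edges_from(zip(edges["source"], edges["target"]))
    degree = pd.DataFrame(
        sorted(graph.degree, key=lambda kv: (-kv[1], kv[0])),
        columns=["feature", "degree"],
    )
    return edges.reset_index(drop=True), degree


def interaction_design_size(P: int, K: int) -> int:
    """Columns an explicit design matrix needs for all interactions up to order K.

    ``sum_{k=1..K} C(P, k)`` — what methods that multiply interaction columns
    into the design must allocate; screening on decision paths keeps the
    original ``P`` columns instead.  The ratio ``size / P`` is the memory
    efficiency factor.
    """
    from math import comb

    if K < 1 or K > P:
        raise ValidationError(f"need 1 <= K <= P, got K={K}, P={P}")
    return sum(comb(P, k) for k in range(1, K + 1))
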