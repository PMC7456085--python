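"""False-discovery-rate adjustment helpers.

Benjamini–Yekutieli (valid under arbitrary dependence, harmonic inflation
factor ``c(M) = sum_{i<=M} 1/i``) is the default; Benjamini–Hochberg and
"none" are exposed for sensitivity analysis.  The standard case delegates to
statsmodels.  ``family_size`` > len(pvalues) supports testing an observed
subset of a declared larger hypothesis family: the unobserved members are
implicit p = 1 entries, which can only enter the step-up minimum at the top
rank where they are dominated by the cap at 1.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

__all__ = ["adjust_pvalues"]

_METHOD_MAP = {"by": "fdr_by", "bh": "fdr_bh"}

_EULER_GAMMA = 0.5772156649015329


def _harmonic(M: int) -> float:
    """c(M) = sum_{i=1..M} 1/i; asymptotic expansion for very large families."""
    if M <= 10**6:
        return float(np.sum(1.0 / np.arange(1, M + 1)))
    return float(np.log(M) + _EULER_GAMMA + 1.0 / (2 * M) - 1.0 / (12 * M**2))


def adjust_pvalues(
    pvalues: Sequence[float],
    method: str = "BY",
    family_size: Optional[int] = None,
) -> np.ndarray:
    """Step-up adjusted p-values, returned in the input order.

    Monotone over the sorted raw p-values, capped at 1, and elementwise
    >= the raw values.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValidationError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    key = method.lower()
    if key == "none":
        return p.copy()
    if key not in _METHOD_MAP:
        raise ValidationError(f"unknown fdr method {method!r} (use BY, BH or none)")
    M = int(family_size) if family_size is not None else p.size
    if M < p.size:
        raise ValidationError("family_size must be >= number of p-values")
    if M == p.size:
        return multipletests(p, method=_METHOD_MAP[key])[1]
    # explicit step-up against the declared family of size M
    scale = float(M) * (_harmonic(M) if key == "by" else 1.0)
    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, p.size + 1)
    stepped = np.minimum.accumulate((scale * p[order] / ranks)[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(stepped, 1.0)
    return out
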