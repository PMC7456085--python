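"""Exchangeable correlated binomial distributions.

The number of trees (out of ``V``) whose root splits on a given feature is a
sum of identically distributed Bernoulli indicators, one per tree.  Trees are
not independent — every tree resamples cases from the same data set — so the
sum is modelled as a *correlated* binomial: ``V`` exchangeable Bernoulli(p)
trials with a single pairwise correlation ``rho``.

Two published formulations of such a distribution are provided:

``witt``
    A "simple" exchangeable family specified by geometrically decaying joint
    success moments ``E[X_1 ... X_j] = p * (p + rho*(1-p))**(j-1)``.  This is
    the unique geometric-moment family that preserves the marginal mean
    ``V*p`` and the pairwise correlation ``rho`` exactly, and it admits a
    closed-form pmf (derived below), so it is numerically robust up to
    thousands of trials.  At ``rho=0`` it reduces exactly to Binomial(V, p);
    at ``rho -> 1`` it degenerates to the all-or-nothing two-point law.

``kuk``
    Kuk's q-power model for exchangeable binary data: the probability that
    any ``j`` specified trials all *fail* is ``q**(j**gamma)`` with
    ``q = 1-p`` and ``gamma`` in (0, 1] chosen to match ``rho``.  The pmf is
    an alternating inclusion–exclusion sum that cancels catastrophically in
    double precision for large ``V``, so it is evaluated in multi-precision
    arithmetic (``precision`` bits, default 1024).

Closed form for the witt model (r = p + rho*(1-p)):

    P(F = k) = C(V, k) * p * r**(k-1) * (1-r)**(V-k)      for k >= 1
    P(F = 0) = 1 - (p/r) * (1 - (1-r)**V)

which follows from the binomial inversion of the geometric moment sequence:
``sum_i (-1)**i C(V-k, i) r**i = (1-r)**(V-k)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import mpmath
import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln

from .errors import DegenerateDistributionError, ValidationError

__all__ = [
    "CorrBinomSpec",
    "validate_spec",
    "pmf",
    "pmf_vector",
    "cdf",
    "upper_tail",
    "quantile",
]

#: magnitude below which negative pmf values are treated as round-off and clipped
NEGATIVE_MASS_TOL = 1e-12
#: allowed deviation of the total mass from 1
NORMALIZATION_TOL = 1e-8

_MODELS = ("witt", "kuk")


@dataclass(frozen=True)
class CorrBinomSpec:
    """Parameters of the exchangeable correlated binomial null.

    Parameters
    ----------
    trials
        Number of Bernoulli trials ``V`` (trees in the forest), >= 1.
    success_prob
        Per-trial success probability ``p`` in (0, 1); for root splits this
        is ``p_root = 1/P``.
    correlation
        Pairwise trial correlation ``rho`` in [0, 1).  ``rho = 0`` recovers
        the ordinary binomial exactly.
    model
        ``"witt"`` (default) or ``"kuk"``; see module docstring.
    precision
        Working precision in bits for the ``kuk`` alternating sums.
    """

    trials: int
    success_prob: float
    correlation: float = 0.0
    model: str = "witt"
    precision: int = field(default=1024, compare=True)

    def __post_init__(self) -> None:
        if not isinstance(self.trials, (int, np.integer)) or self.trials < 1:
            raise ValidationError(f"trials must be a positive integer, got {self.trials!r}")
        if not 0.0 < float(self.success_prob) < 1.0:
            raise ValidationError(
                f"success_prob must lie strictly in (0, 1), got {self.success_prob!r}"
            )
        if not 0.0 <= float(self.correlation) < 1.0:
            raise ValidationError(
                f"correlation must lie in [0, 1), got {self.correlation!r}"
            )
        if self.model not in _MODELS:
            raise ValidationError(f"model must be one of {_MODELS}, got {self.model!r}")
        if self.precision < 53:
            raise ValidationError("precision must be at least 53 bits")

    def to_dict(self) -> dict:
        return {
            "trials": int(self.trials),
            "success_prob": float(self.success_prob),
            "correlation": float(self.correlation),
            "model": self.model,
        }


def _witt_log_pmf_tail(spec: CorrBinomSpec) -> np.ndarray:
    """log pmf at k = 1..V for the witt closed form (k = 0 handled separately)."""
    n = spec.trials
    p = float(spec.success_prob)
    rho = float(spec.correlation)
    r = p + rho * (1.0 - p)
    k = np.arange(1, n + 1, dtype=float)
    log_comb = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    # log(1-r) via log1p of -r; r < 1 is guaranteed because rho < 1, p < 1
    return log_comb + math.log(p) + (k - 1.0) * math.log(r) + (n - k) * math.log1p(-r)


def _witt_pmf_vector(spec: CorrBinomSpec) -> np.ndarray:
    n = spec.trials
    p = float(spec.success_prob)
    rho = float(spec.correlation)
    r = p + rho * (1.0 - p)
    out = np.empty(n + 1)
    out[1:] = np.exp(_witt_log_pmf_tail(spec))
    # P(0) = 1 - (p/r) * (1 - (1-r)^n), computed via expm1 for accuracy
    out[0] = 1.0 + (p / r) * math.expm1(n * math.log1p(-r))
    return out


def _kuk_gamma(p: float, rho: float) -> float:
    """Solve q^(2^gamma) - q^2 = rho*p*q for gamma in (0, 1]."""
    if rho == 0.0:
        return 1.0
    q = 1.0 - p

    def f(gamma: float) -> float:
        return q ** (2.0**gamma) - q * q - rho * p * q

    # f is decreasing in gamma: f(1) = -rho*p*q < 0, f(0+) = pq(1-rho) > 0
    return brentq(f, 1e-12, 1.0, xtol=1e-15)


def _kuk_pmf_vector(spec: CorrBinomSpec) -> np.ndarray:
    """Inclusion–exclusion over all-failure probabilities eta_j = q^(j^gamma).

    P(F = k) = C(n,k) * sum_{i=0..k} (-1)^i C(k,i) eta_{n-k+i}
    evaluated at ``spec.precision`` bits to tame the alternating cancellation.
    """
    n = spec.trials
    p = float(spec.success_prob)
    gamma = _kuk_gamma(p, float(spec.correlation))
    with mpmath.workprec(spec.precision):
        q = mpmath.mpf(1) - mpmath.mpf(p)
        eta = [mpmath.power(q, mpmath.power(j, gamma)) if j else mpmath.mpf(1)
               for j in range(n + 1)]
        out = np.empty(n + 1)
        for k in range(n + 1):
            acc = mpmath.mpf(0)
            c = mpmath.mpf(1)  # running C(k, i), signed
            for i in range(k + 1):
                acc += c * eta[n - k + i]
                c = -c * (k - i) / (i + 1)
            out[k] = float(mpmath.binomial(n, k) * acc)
    return out


@lru_cache(maxsize=128)
def _pmf_vector_cached(spec: CorrBinomSpec) -> np.ndarray:
    if spec.model == "witt":
        vec = _witt_pmf_vector(spec)
    else:
        vec = _kuk_pmf_vector(spec)
    neg = vec.min()
    if neg < -NEGATIVE_MASS_TOL:
        raise DegenerateDistributionError(
            f"(trials={spec.trials}, p={spec.success_prob}, rho={spec.correlation}, "
            f"model={spec.model}) is not a valid distribution: pmf reaches {neg:.3e}"
        )
    vec = np.clip(vec, 0.0, None)
    total = vec.sum()
    if abs(total - 1.0) > NORMALIZATION_TOL:
        raise DegenerateDistributionError(
            f"pmf of (trials={spec.trials}, p={spec.success_prob}, "
            f"rho={spec.correlation}, model={spec.model}) sums to {total!r}"
        )
    vec.setflags(write=False)
    return vec


def validate_spec(spec: CorrBinomSpec) -> CorrBinomSpec:
    """Return ``spec`` unchanged if it defines a valid probability distribution.

    Runs the full-support pmf scan: every mass must be >= -1e-12 (smaller
    negatives are clipped as round-off) and the total must be within 1e-8 of
    one.  Raises :class:`ValidationError` for malformed parameters and
    :class:`DegenerateDistributionError` for invalid (p, rho, V) combinations.
    """
    _pmf_vector_cached(spec)
    return spec


def pmf_vector(spec: CorrBinomSpec) -> np.ndarray:
    """Probability mass at every k in 0..trials (read-only array)."""
    return _pmf_vector_cached(spec)


def _check_k(spec: CorrBinomSpec, k: int) -> int:
    k = int(k)
    if not 0 <= k <= spec.trials:
        raise ValidationError(f"k must lie in [0, {spec.trials}], got {k}")
    return k


def pmf(spec: CorrBinomSpec, k: int) -> float:
    """P(F = k)."""
    return float(pmf_vector(spec)[_check_k(spec, k)])


def cdf(spec: CorrBinomSpec, k: int) -> float:
    """P(F <= k)."""
    k = _check_k(spec, k)
    return float(min(1.0, pmf_vector(spec)[: k + 1].sum()))


def upper_tail(spec: CorrBinomSpec, k: int) -> float:
    """One-sided exceedance probability P(F >= k); the test's raw p-value.

    Summed from the top of the support so that extreme tails keep full
    relative accuracy.
    """
    k = _check_k(spec, k)
    if k == 0:
        return 1.0
    return float(min(1.0, pmf_vector(spec)[k:].sum()))


def upper_tail_vector(spec: CorrBinomSpec) -> np.ndarray:
    """P(F >= k) for every k in 0..trials."""
    vec = pmf_vector(spec)
    tail = np.minimum(1.0, np.cumsum(vec[::-1])[::-1])
    tail[0] = 1.0
    return tail


def quantile(spec: CorrBinomSpec, q: float) -> int:
    """Smallest integer k with cdf(k) >= q (the critical value at level q)."""
    if not 0.0 < q < 1.0:
        raise ValidationError(f"quantile level must lie in (0, 1), got {q!r}")
    cum = np.cumsum(pmf_vector(spec))
    idx = int(np.searchsorted(cum, q - 1e-15, side="left"))
    return min(idx, spec.trials)
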