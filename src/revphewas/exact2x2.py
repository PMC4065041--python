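"""Exact inference for 2x2 tables of homozygote disease counts.

The screening and matched-control stages both reduce to a 2x2 table

                 affected   unaffected
    minor HZ        a         n1 - a
    common HZ       b         n0 - b

comparing minor-allele homozygotes (``n1`` subjects, ``a`` affected) to
common-allele homozygotes (``n0``, ``b``).  Conditioning on both margins,
the affected-minor-homozygote count ``A`` follows Fisher's noncentral
hypergeometric distribution indexed by the odds ratio ``psi``:

    P(A = k | psi)  ∝  C(n1, k) C(n0, m - k) psi**k,   m = a + b,

with support ``k in [max(0, m - n0), min(n1, m)]``.  All quantities here —
the two-sided Fisher p-value, the conditional maximum-likelihood odds
ratio (CMLE), the boundary-safe median-unbiased estimate (MUE), and the
exact tail-inversion confidence interval — are derived from this one
likelihood.  Exact conditional inference with a single binary exposure is
identical to univariate exact logistic regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln

__all__ = [
    "fisher_exact_two_sided",
    "fisher_exact_batch",
    "odds_ratio_crude",
    "exact_2x2_inference",
    "Exact2x2Result",
]

# Relative tolerance when comparing table probabilities in the two-sided
# probability method; guards against ties lost to floating-point rounding.
_TIE_RTOL = 1e-7

# log psi is searched within [-_LOG_PSI_MAX, _LOG_PSI_MAX].
_LOG_PSI_MAX = 80.0


def _check_counts(a: int, n1: int, b: int, n0: int) -> None:
    for v in (a, n1, b, n0):
        if v < 0 or v != int(v):
            raise ValueError(f"counts must be non-negative integers, got {(a, n1, b, n0)}")
    if a > n1 or b > n0:
        raise ValueError(f"affected counts exceed totals: {(a, n1, b, n0)}")


def _log_binom(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def _support_weights(n1: int, n0: int, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Support of A and log C(n1,k) + C(n0,m-k) over it."""
    lo = max(0, m - n0)
    hi = min(n1, m)
    k = np.arange(lo, hi + 1)
    lw = _log_binom(np.full_like(k, n1, dtype=float), k.astype(float)) + _log_binom(
        np.full_like(k, n0, dtype=float), (m - k).astype(float)
    )
    return k, lw


def fisher_exact_batch(
    a: np.ndarray, n1: np.ndarray, b: np.ndarray, n0: np.ndarray
) -> np.ndarray:
    """Vectorized two-sided Fisher exact p-values (probability method).

    All four arguments are equal-length integer arrays; returns an array of
    p-values in (0, 1].  Tables whose margins admit a single configuration
    get p = 1.
    """
    a = np.asarray(a, dtype=np.int64)
    n1 = np.asarray(n1, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    n0 = np.asarray(n0, dtype=np.int64)
    if a.size == 0:
        return np.empty(0)
    m = a + b
    lo = np.maximum(0, m - n0)
    hi = np.minimum(n1, m)
    cnt = hi - lo + 1
    offsets = np.concatenate(([0], np.cumsum(cnt)))
    starts = offsets[:-1]
    total = int(offsets[-1])

    # ragged support, flattened
    k = lo.repeat(cnt) + (np.arange(total) - starts.repeat(cnt))
    rn1 = n1.repeat(cnt).astype(float)
    rn0 = n0.repeat(cnt).astype(float)
    rm = m.repeat(cnt).astype(float)
    kf = k.astype(float)
    lw = _log_binom(rn1, kf) + _log_binom(rn0, rm - kf)

    seg_max = np.maximum.reduceat(lw, starts)
    w = np.exp(lw - seg_max.repeat(cnt))
    seg_sum = np.add.reduceat(w, starts)
    pmf = w / seg_sum.repeat(cnt)

    p_obs = pmf[starts + (a - lo)]
    included = pmf <= p_obs.repeat(cnt) * (1.0 + _TIE_RTOL)
    p = np.add.reduceat(np.where(included, pmf, 0.0), starts)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def fisher_exact_two_sided(a: int, n1: int, b: int, n0: int) -> float:
    """Two-sided Fisher exact p comparing a/n1 against b/n0.

    Probability method: the p-value sums, over all tables sharing the
    observed margins, the hypergeometric probabilities no larger than that
    of the observed table (to relative tolerance 1e-7).
    """
    _check_counts(a, n1, b, n0)
    if n1 + n0 == 0:
        raise ValueError("empty table: n1 + n0 must be positive")
    return float(fisher_exact_batch(np.array([a]), np.array([n1]), np.array([b]), np.array([n0]))[0])


def odds_ratio_crude(a: int, n1: int, b: int, n0: int) -> float:
    """Cross-product (unconditional) odds ratio (a/(n1-a)) / (b/(n0-b)).

    Returns ``nan`` when undefined: a == n1, b == n0, or a == b == 0.
    """
    _check_counts(a, n1, b, n0)
    if a == n1 or b == n0 or (a == 0 and b == 0):
        return math.nan
    if b == 0:
        return math.inf
    return (a / (n1 - a)) / (b / (n0 - b))


def _tail_ge(t: float, k: np.ndarray, lw: np.ndarray, a: int) -> float:
    """P(A >= a | log psi = t)."""
    logw = lw + k * t
    w = np.exp(logw - logw.max())
    return float(w[k >= a].sum() / w.sum())


def _tail_le(t: float, k: np.ndarray, lw: np.ndarray, a: int) -> float:
    logw = lw + k * t
    w = np.exp(logw - logw.max())
    return float(w[k <= a].sum() / w.sum())


def _mean_a(t: float, k: np.ndarray, lw: np.ndarray) -> float:
    logw = lw + k * t
    w = np.exp(logw - logw.max())
    return float((w * k).sum() / w.sum())


def _solve_log_psi(f, target: float) -> float:
    """Solve f(t) = target for t, where f is strictly monotone in t."""
    g = lambda t: f(t) - target
    lo, hi = -_LOG_PSI_MAX, _LOG_PSI_MAX
    glo, ghi = g(lo), g(hi)
    if glo == 0.0:
        return lo
    if ghi == 0.0:
        return hi
    if glo * ghi > 0:
        # target unreachable within bracket; return the nearer endpoint
        return lo if abs(glo) < abs(ghi) else hi
    return brentq(g, lo, hi, xtol=1e-12, rtol=8.9e-16)


@dataclass(frozen=True)
class Exact2x2Result:
    """Exact conditional inference for one 2x2 table.

    ``or_method`` records how the point estimate was obtained: ``cmle``
    (interior conditional MLE), ``mue`` (median-unbiased, used when the
    CMLE sits at 0 or infinity), or ``undefined`` (no affected minor
    homozygotes, or degenerate margins).
    """

    a: int
    n1: int
    b: int
    n0: int
    or_point: float
    or_method: str
    ci_low: float
    ci_high: float
    p: float

    @property
    def ci(self) -> tuple[float, float]:
        return (self.ci_low, self.ci_high)


def exact_2x2_inference(
    a: int,
    n1: int,
    b: int,
    n0: int,
    confidence: float = 0.95,
    mid_p: bool = False,
) -> Exact2x2Result:
    """Exact conditional odds-ratio inference on a 2x2 table.

    Point estimate: CMLE solving E_psi[A] = a by monotone root finding;
    when ``a`` lies at the edge of the conditional support the CMLE is 0 or
    infinite and a median-unbiased estimate (tail probability = 1/2) is
    substituted.  The confidence interval inverts one-sided exact tail
    tests at (1-confidence)/2 per side; ``mid_p=True`` subtracts half the
    observed-point probability from each tail before inverting.  The
    p-value is the two-sided probability-method test of psi = 1.

    Following the convention of reporting "n/a" when no minor-allele
    homozygote is affected, ``a == 0`` yields ``or_method='undefined'``
    with the p-value still computed; fully degenerate margins (everyone or
    no one affected) yield undefined everything.
    """
    _check_counts(a, n1, b, n0)
    if n1 == 0 or n0 == 0:
        raise ValueError("both homozygote groups must be non-empty")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")

    m = a + b
    degenerate = m == 0 or m == n1 + n0
    if degenerate:
        return Exact2x2Result(a, n1, b, n0, math.nan, "undefined", math.nan, math.nan, math.nan)

    p = fisher_exact_two_sided(a, n1, b, n0)
    if a == 0:
        return Exact2x2Result(a, n1, b, n0, math.nan, "undefined", math.nan, math.nan, p)

    k, lw = _support_weights(n1, n0, m)
    lo_k, hi_k = int(k[0]), int(k[-1])
    alpha2 = (1.0 - confidence) / 2.0

    half = 0.5 if mid_p else 0.0

    def tail_upper(t: float) -> float:  # P(A >= a), decreasing target in psi? increasing.
        v = _tail_ge(t, k, lw, a)
        if mid_p:
            logw = lw + k * t
            w = np.exp(logw - logw.max())
            v -= half * float(w[k == a].sum() / w.sum())
        return v

    def tail_lower(t: float) -> float:  # P(A <= a); decreasing in psi
        v = _tail_le(t, k, lw, a)
        if mid_p:
            logw = lw + k * t
            w = np.exp(logw - logw.max())
            v -= half * float(w[k == a].sum() / w.sum())
        return v

    # point estimate
    if lo_k < a < hi_k:
        t_hat = _solve_log_psi(lambda t: _mean_a(t, k, lw), float(a))
        or_point, method = math.exp(t_hat), "cmle"
    elif a == hi_k:
        t_hat = _solve_log_psi(lambda t: _tail_ge(t, k, lw, a), 0.5)
        or_point, method = math.exp(t_hat), "mue"
    else:  # a == lo_k > 0
        t_hat = _solve_log_psi(lambda t: _tail_le(t, k, lw, a), 0.5)
        or_point, method = math.exp(t_hat), "mue"

    # exact tail-inversion CI
    if a == lo_k:
        ci_low = 0.0
    else:
        ci_low = math.exp(_solve_log_psi(tail_upper, alpha2))
    if a == hi_k:
        ci_high = math.inf
    else:
        ci_high = math.exp(_solve_log_psi(tail_lower, alpha2))

    return Exact2x2Result(a, n1, b, n0, or_point, method, ci_low, ci_high, p)
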