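"""Positive false discovery rate (q-values) with pi0 estimation.

q(p) is the minimum positive FDR at which a test with p-value p is called
significant. The proportion of true nulls pi0 is estimated from the
flat right tail of the p-value histogram: pi0(lambda) = #{p > lambda} /
(m (1 - lambda)) on a lambda grid, smoothed by a cubic fit and read off
at the largest lambda. With pi0 = 1 the q-values reduce exactly to
Benjamini-Hochberg adjusted p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["QValueResult", "estimate_pi0", "qvalues", "qvalue_result"]

DEFAULT_LAMBDA = np.arange(0.05, 0.901, 0.05)


@dataclass
class QValueResult:
    p_values: np.ndarray
    lambda_grid: np.ndarray
    pi0_lambda: np.ndarray
    pi0: float
    q_values: np.ndarray


def _check_p(p):
    p = np.asarray(p, dtype=float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def estimate_pi0(p_values, lambda_grid=None):
    """Smoother estimate of the true-null proportion pi0.

    For small families (m < 100) the tail estimates are too unstable and
    the conservative pi0 = 1 is returned, making the q-values equal to
    Benjamini-Hochberg.
    """
    p = _check_p(p_values)
    m = p.size
    lam = DEFAULT_LAMBDA if lambda_grid is None else np.asarray(lambda_grid)
    if m < 100:
        return 1.0
    pi0_lam = np.array([np.mean(p > l) / (1.0 - l) for l in lam])
    # cubic least-squares fit stands in for the df=3 smoothing spline
    coef = np.polynomial.polynomial.polyfit(lam, pi0_lam, 3)
    pi0 = float(np.polynomial.polynomial.polyval(lam.max(), coef))
    return float(np.clip(pi0, 0.0, 1.0))


def qvalues(p_values, pi0=None):
    """Storey q-values, returned in the input order.

    With p sorted ascending, q_(m) = min(pi0 * p_(m), 1) and
    q_(i) = min(pi0 * m * p_(i) / i, q_(i+1)).
    """
    p = _check_p(p_values)
    if pi0 is None:
        pi0 = estimate_pi0(p)
    if not 0.0 <= pi0 <= 1.0:
        raise ValueError("pi0 must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ps = p[order]
    q = pi0 * m * ps / np.arange(1, m + 1)
    q = np.minimum(q, 1.0)
    q = np.minimum.accumulate(q[::-1])[::-1]
    out = np.empty_like(q)
    out[order] = q
    return out


def qvalue_result(p_values, lambda_grid=None, pi0=None) -> QValueResult:
    """Full record: pi0(lambda) sequence, pi0 estimate, and q-values."""
    p = _check_p(p_values)
    lam = DEFAULT_LAMBDA if lambda_grid is None else np.asarray(lambda_grid)
    pi0_lam = np.array([np.mean(p > l) / (1.0 - l) for l in lam])
    pi0_est = estimate_pi0(p, lam) if pi0 is None else float(pi0)
    return QValueResult(p_values=p, lambda_grid=lam, pi0_lambda=pi0_lam,
                        pi0=pi0_est, q_values=qvalues(p, pi0_est))
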