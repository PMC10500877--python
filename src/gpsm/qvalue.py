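"""Storey q-values with smoother-based estimation of pi0.

pi0 (the proportion of true nulls) is estimated on the lambda grid
0.05, 0.10, ..., 0.95 as pi0(lambda) = #{p > lambda} / (m (1 - lambda)),
smoothed with a cubic fit and evaluated at the largest lambda, then clamped
to (0, 1]. q-values are pi0 * m * p / rank, monotonised from the largest
p-value downward, so equal p-values always receive equal q-values.

With fewer than 100 p-values the smoother is unreliable and the estimator
falls back to pi0 = 1 (plain Benjamini-Hochberg) with a warning.
"""

from __future__ import annotations

import warnings

import numpy as np

_LAMBDAS = np.arange(0.05, 0.951, 0.05)


def estimate_pi0(p: np.ndarray, lambdas: np.ndarray = _LAMBDAS) -> float:
    """Smoother estimate of the null proportion pi0."""
    p = np.asarray(p, dtype=float)
    m = p.size
    counts = np.array([(p > lam).sum() for lam in lambdas], dtype=float)
    pi0_lam = counts / (m * (1.0 - lambdas))
    coef = np.polyfit(lambdas, pi0_lam, deg=3)
    pi0 = float(np.polyval(coef, lambdas.max()))
    return min(max(pi0, 1.0 / m), 1.0)


def qvalues(p, pi0: float | None = None) -> np.ndarray:
    """FDR q-values for a vector of p-values in (0, 1]."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-D array")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size

    if pi0 is None:
        if m < 100:
            warnings.warn(
                f"only {m} p-values; falling back to pi0 = 1 "
                "(Benjamini-Hochberg)", stacklevel=2
            )
            pi0 = 1.0
        else:
            pi0 = estimate_pi0(p)
    if not 0 < pi0 <= 1:
        raise ValueError(f"pi0 must be in (0, 1], got {pi0}")

    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    raw = pi0 * m * p[order] / ranks
    # monotonise from the largest p-value down
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
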