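"""Storey q-values, pi0 / pi1 estimation.

pi0 (the proportion of true nulls) is estimated with Storey's smoother:
the tail estimate #{p > lambda} / (m (1 - lambda)) is computed on a grid of
lambda values, a cubic smoothing spline is fit, and the spline is evaluated
at the largest lambda. q-values are the usual step-up transform scaled by
pi0. pi1 = 1 - pi0 is the standard estimate of the fraction of true signals
in a p-value set (used for cross-cell-type QTL sharing).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.interpolate import UnivariateSpline

__all__ = ["storey_pi0", "storey_qvalue", "storey_pi1"]

DEFAULT_LAMBDA_GRID = np.arange(0.05, 0.951, 0.05)

# Below this many p-values the tail counts behind pi0 are too unstable;
# fall back to pi0 = 1 (plain Benjamini-Hochberg).
MIN_TESTS_FOR_PI0 = 20


def storey_pi0(p: np.ndarray, lambda_grid: np.ndarray | None = None) -> float:
    """Estimate the null proportion pi0 from p-values via Storey's smoother."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m < MIN_TESTS_FOR_PI0:
        warnings.warn(
            f"only {m} p-values (< {MIN_TESTS_FOR_PI0}); "
            "falling back to pi0 = 1 (Benjamini-Hochberg)",
            UserWarning,
            stacklevel=2,
        )
        return 1.0
    lam = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid, float)
    pi0_lam = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
    # cubic smoothing spline evaluated at the largest lambda (Storey 2002)
    spline = UnivariateSpline(lam, pi0_lam, k=3)
    pi0 = float(spline(lam.max()))
    return float(np.clip(pi0, 1e-4, 1.0))


def storey_qvalue(
    p: np.ndarray, lambda_grid: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Return (pi0, q-values) for a vector of p-values.

    q_(i) = min_{j >= i} pi0 * m * p_(j) / j over the sorted p-values.
    """
    p = np.asarray(p, dtype=float).ravel()
    pi0 = storey_pi0(p, lambda_grid)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return pi0, q


def storey_pi1(p: np.ndarray, lambda_grid: np.ndarray | None = None) -> float:
    """Fraction of true signals, 1 - pi0."""
    return 1.0 - storey_pi0(p, lambda_grid)
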