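"""Storey q-values for false-discovery-rate control.

The q-value of a test is the minimum FDR at which that test would be
called significant.  Unlike Benjamini-Hochberg, Storey's procedure
estimates the proportion of true nulls, pi0, from the flat right tail of
the p-value histogram and scales the adjusted p-values by it; with
pi0 = 1 the two procedures coincide exactly.
"""

from __future__ import annotations

import numpy as np

__all__ = ["estimate_pi0", "storey_qvalues"]

#: lambda grid used for the pi0 tail fit, 0.05 .. 0.95
_LAMBDA_GRID = np.arange(0.05, 0.96, 0.05)

#: below this many p-values the tail estimate is too unstable; use pi0 = 1
_MIN_N_FOR_PI0 = 100


def estimate_pi0(pvalues: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Estimate the proportion of true null hypotheses, pi0.

    For each lambda, ``pi0(lambda) = #{p > lambda} / (m * (1 - lambda))``;
    the raw estimates are smoothed with a cubic least-squares fit over the
    lambda grid and read off at the largest lambda, where the bias from
    true alternatives vanishes.  The result is clipped to (0, 1].

    With fewer than 100 p-values the tail is too sparse to smooth and the
    conservative ``pi0 = 1`` is returned.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("cannot estimate pi0 from an empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if p.size < _MIN_N_FOR_PI0:
        return 1.0
    lam = _LAMBDA_GRID if lambdas is None else np.asarray(lambdas, dtype=float)
    raw = np.array([np.mean(p > lv) / (1.0 - lv) for lv in lam])
    # cubic smoother over the grid, evaluated at the right end
    coef = np.polynomial.polynomial.polyfit(lam, raw, deg=3)
    pi0 = float(np.polynomial.polynomial.polyval(lam[-1], coef))
    return float(min(max(pi0, 1.0 / p.size), 1.0))


def storey_qvalues(pvalues: np.ndarray, pi0: float | None = None) -> np.ndarray:
    """Storey q-values for a collection of p-values.

    Parameters
    ----------
    pvalues
        p-values in (0, 1].
    pi0
        Proportion of true nulls.  Estimated from the data when None;
        pass ``pi0=1`` to recover Benjamini-Hochberg adjusted p-values.

    Returns
    -------
    q-values in the input order; monotone non-decreasing in p and <= 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("cannot compute q-values for an empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    if not 0 < pi0 <= 1:
        raise ValueError(f"pi0 must be in (0, 1], got {pi0}")

    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    # step-up: q_(i) = min_{j >= i} pi0 * m * p_(j) / j
    q_sorted = np.minimum.accumulate((pi0 * m * ranked / np.arange(1, m + 1))[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q
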