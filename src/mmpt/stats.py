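"""Shared statistical primitives.

Spearman correlation with exact small-sample permutation p-values,
Storey's q-value FDR procedure, and Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from itertools import permutations
from typing import NamedTuple

import numpy as np
from scipy import stats as sps

__all__ = [
    "SpearmanResult",
    "spearman",
    "storey_qvalues",
    "bh_adjust",
]

#: Below this sample size the permutation null is enumerated exactly.
EXACT_PERMUTATION_MAX_N = 8

#: Floor applied to p-values before taking log10.
P_FLOOR = 1e-300


class SpearmanResult(NamedTuple):
    rho: float
    p: float
    n: int
    exact: bool


def _rank(a: np.ndarray) -> np.ndarray:
    return sps.rankdata(a)


def spearman(x, y, *, exact_max_n: int = EXACT_PERMUTATION_MAX_N) -> SpearmanResult:
    """Spearman rank correlation with a two-sided p-value.

    For ``n <= exact_max_n`` complete pairs the p-value is computed by
    exact enumeration of all ``n!`` rank permutations; otherwise the
    standard t-distribution approximation is used. Pairs with a missing
    member are dropped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        return SpearmanResult(np.nan, np.nan, n, False)
    rx, ry = _rank(x), _rank(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return SpearmanResult(np.nan, np.nan, n, False)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        p = _exact_permutation_p(rx, ry, rho)
        return SpearmanResult(rho, p, n, True)
    # t approximation, guarded at |rho| = 1
    if abs(rho) >= 1.0:
        return SpearmanResult(float(np.sign(rho)), 0.0, n, False)
    t = rho * np.sqrt((n - 2) / (1 - rho * rho))
    p = float(2 * sps.t.sf(abs(t), df=n - 2))
    return SpearmanResult(rho, min(p, 1.0), n, False)


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    n = rx.size
    sx = np.std(rx)
    hits = 0
    total = 0
    thresh = abs(rho_obs) - 1e-12
    rxc = rx - rx.mean()
    for perm in permutations(range(n)):
        ryp = ry[list(perm)]
        ryc = ryp - ryp.mean()
        rho = float(rxc @ ryc) / (n * sx * np.std(ryp))
        total += 1
        if abs(rho) >= thresh:
            hits += 1
    return hits / total


def signed_logp(rho: float, p: float) -> float:
    """sign(rho) * -log10(p), with p floored to avoid -inf."""
    return float(np.sign(rho) * -np.log10(max(p, P_FLOOR)))


def storey_qvalues(pvalues, *, lambdas=None, pi0: float | None = None) -> np.ndarray:
    """Storey q-values with a smoother-based pi0 estimate.

    pi0 is estimated on a lambda grid (default 0.05..0.95 step 0.05) via
    a cubic-polynomial smoother evaluated at the largest lambda, then
    clipped to (0, 1]. Pass ``pi0`` to override the estimate.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        if lambdas is None:
            lambdas = np.arange(0.05, 0.96, 0.05)
        lambdas = np.asarray(lambdas, dtype=float)
        if m < 100 or lambdas.size < 4:
            pi0 = 1.0
        else:
            pi0_lambda = np.array(
                [np.mean(p > lam) / (1 - lam) for lam in lambdas]
            )
            coef = np.polyfit(lambdas, pi0_lambda, 3)
            pi0 = float(np.polyval(coef, lambdas.max()))
    pi0 = float(np.clip(pi0, 1.0 / m, 1.0))
    order = np.argsort(p)
    ranked = p[order]
    q = pi0 * ranked * m / (np.arange(m) + 1)
    # enforce monotonicity from the largest p down
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return storey_qvalues(pvalues, pi0=1.0)
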