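"""Small exact-test helpers shared across modules."""

from __future__ import annotations

import numpy as np
from scipy import stats


def poisson_two_sided_p(k: int, lam: float) -> float:
    """Exact two-sided Poisson test by the minimum-likelihood method.

    The p-value is the total probability of all outcomes whose likelihood
    under Poisson(lam) does not exceed that of the observed ``k`` (with a
    small relative slack so that the observed outcome itself is always
    included despite floating-point rounding).
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if lam == 0:
        return 1.0 if k == 0 else 0.0
    k = int(k)
    p_obs = stats.poisson.pmf(k, lam)
    if p_obs == 0.0:
        return 0.0
    hi = int(max(k, lam + 12 * np.sqrt(lam) + 20))
    ks = np.arange(0, hi + 1)
    pmf = stats.poisson.pmf(ks, lam)
    total = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    # tail above the enumeration limit is entirely less likely than k
    total += float(stats.poisson.sf(hi, lam))
    return min(total, 1.0)


def binom_two_sided_p(k: int, n: int, p: float) -> float:
    """Exact two-sided binomial test (minimum-likelihood method)."""
    if n == 0:
        return 1.0
    return float(stats.binomtest(int(k), int(n), p).pvalue)


def fisher_two_sided(table) -> tuple[float, float]:
    """Two-sided Fisher exact test; returns (odds ratio, p)."""
    odds, p = stats.fisher_exact(np.asarray(table), alternative="two-sided")
    return float(odds), float(p)
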