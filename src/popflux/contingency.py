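"""Exact and chi-square tests for 2x2 contingency tables.

The Fisher exact test is computed from the hypergeometric distribution
with the two-tailed point-probability rule (sum the probabilities of every
table with the observed margins whose probability does not exceed that of
the observed table, up to a small relative slack for ties); the chi-square
test uses the closed-form 2x2 statistic without continuity correction.
"""

from __future__ import annotations

from scipy.stats import chi2, hypergeom

# Relative slack for tie detection in the two-tailed sum; matches the
# convention of R's fisher.test and scipy.
_RELATIVE_TIE_SLACK = 1.0 + 1e-7


def fisher_exact_2x2(a: int, b: int, c: int, d: int,
                     mode: str = "two_tailed") -> float:
    """Fisher exact p-value for the table [[a, b], [c, d]].

    ``mode`` is ``two_tailed`` (point-probability rule), ``less`` or
    ``greater`` (one-tailed on cell ``a``).  Any zero margin gives p = 1.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("cells must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    N = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == N or c1 == N:
        return 1.0
    dist = hypergeom(N, r1, c1)
    lo = max(0, r1 + c1 - N)
    hi = min(r1, c1)
    if mode == "less":
        return float(min(1.0, dist.cdf(a)))
    if mode == "greater":
        return float(min(1.0, dist.sf(a - 1)))
    if mode != "two_tailed":
        raise ValueError(f"unknown mode {mode!r}")
    import numpy as np
    support = np.arange(lo, hi + 1)
    pmf = dist.pmf(support)
    p_obs = pmf[a - lo]
    total = pmf[pmf <= p_obs * _RELATIVE_TIE_SLACK].sum()
    return float(min(1.0, total))


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square without continuity correction on [[a,b],[c,d]].

    Returns (statistic, p) with the closed form
    N*(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); a zero margin gives (0, 1).
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("cells must be non-negative")
    N = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0, 1.0
    stat = N * (a * d - b * c) ** 2 / denom
    return float(stat), float(chi2.sf(stat, df=1))
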