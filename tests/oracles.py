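"""Independent exact-arithmetic oracles for the exact conditional tests.

These enumerate the full outcome space with Python integers (math.comb),
compare probability-mass numerators over the common denominator, and
implement the 1 + 1e-7 relative guard in exact integer arithmetic — no
floating point enters until the final ratio.  They share no code with the
package implementations they check.
"""

from __future__ import annotations

from bisect import bisect_right
from itertools import accumulate
from math import comb

# guard 1 + 1e-7 as the exact rational GN/GD
GN, GD = 10**7 + 1, 10**7


def fisher_oracle_family(r1: int, r2: int, c1: int) -> tuple[int, list[float]]:
    """Two-sided Fisher p for every table with the given margins.

    Returns (lo, pvalues) with pvalues[i] for the table having
    n11 = lo + i.  Probability-mass convention: sum hypergeometric
    numerators comb(r1, k) * comb(r2, c1 - k) over all k whose numerator
    is <= observed * (1 + 1e-7), divided by comb(r1 + r2, c1).
    """
    lo, hi = max(0, c1 - r2), min(r1, c1)
    nums = [comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)]
    total = sum(nums)
    order = sorted(range(len(nums)), key=nums.__getitem__)
    sorted_nums = [nums[i] for i in order]
    csum = list(accumulate(sorted_nums))
    out = []
    for v in nums:
        # integers: sorted_nums[j] <= v * GN / GD  <=>  <= floor(v * GN / GD)
        pos = bisect_right(sorted_nums, (v * GN) // GD)
        out.append(csum[pos - 1] / total)
    return lo, out


def fisher_oracle(n11: int, n12: int, n21: int, n22: int) -> float:
    """Two-sided Fisher p for one table by exhaustive enumeration."""
    r1, r2, c1 = n11 + n12, n21 + n22, n11 + n21
    if r1 == 0 or r2 == 0 or c1 == 0 or n12 + n22 == 0:
        return 1.0
    lo, pvalues = fisher_oracle_family(r1, r2, c1)
    return pvalues[n11 - lo]


def binomial_oracle(x1: int, x2: int, n1_total: int, n2_total: int) -> float:
    """Exact two-sided conditional binomial p by full enumeration.

    x1 ~ Binomial(x1 + x2, n1_total / (n1_total + n2_total)) under the
    null; outcome-probability numerators are comb(n, j) * N1^j * N2^(n-j)
    over the common denominator (N1 + N2)^n.
    """
    n = x1 + x2
    nums = [comb(n, j) * n1_total**j * n2_total ** (n - j) for j in range(n + 1)]
    total = sum(nums)
    obs = nums[x1]
    kept = sum(v for v in nums if v * GD <= obs * GN)
    return kept / total
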