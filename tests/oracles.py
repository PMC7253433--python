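"""Independent reference implementations used only by the test suite."""

from fractions import Fraction
from math import comb


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration in
    exact rational arithmetic.

    At fixed margins the table probability is
    C(n1, x) * C(n2, k - x) / C(n1 + n2, k); the two-sided p sums the
    probabilities of all tables no more likely than the observed one.
    """
    n1, n2, k = a + b, c + d, a + c
    if n1 == 0 or n2 == 0 or k == 0 or k == n1 + n2:
        return Fraction(1)
    denom = comb(n1 + n2, k)
    lo, hi = max(0, k - n2), min(n1, k)
    weights = {x: comb(n1, x) * comb(n2, k - x) for x in range(lo, hi + 1)}
    w_obs = weights[a]
    total = sum(w for w in weights.values() if w <= w_obs)
    return Fraction(total, denom)
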