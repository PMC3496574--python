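"""Independent brute-force oracles used to pin expected values.

Everything here works in exact integer/rational arithmetic and enumerates
definitions directly; nothing is shared with the package's implementation
paths.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import product
from math import comb


def fisher_p_exact(table) -> Fraction:
    """Exact two-sided Fisher p-value (probability method) for a 2×k table.

    Brute force: enumerate every top row compatible with the column sums,
    weight each by its product of binomial coefficients (the multivariate
    hypergeometric numerator), and sum the weights ≤ the observed weight.
    """
    top = [int(x) for x in table[0]]
    bot = [int(x) for x in table[1]]
    cols = [a + b for a, b in zip(top, bot)]
    r0 = sum(top)

    def weight(t):
        w = 1
        for cj, aj in zip(cols, t):
            w *= comb(cj, aj)
        return w

    obs = weight(top)
    acc = 0
    tot = 0
    for t in product(*(range(min(cj, r0) + 1) for cj in cols)):
        if sum(t) != r0:
            continue
        w = weight(t)
        tot += w
        if w <= obs:
            acc += w
    return Fraction(acc, tot) if tot else Fraction(1)


def bh_adjust_exact(p_values) -> list[Fraction]:
    """Benjamini–Hochberg step-up from its definition, in input order:
    q(i) = min over j with p(j) ranked ≥ rank(i) of min(1, m·p(j)/j)."""
    ps = [Fraction(p).limit_denominator(10**12) if not isinstance(p, Fraction) else p
          for p in p_values]
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    q_sorted: list[Fraction] = [Fraction(0)] * m
    running = Fraction(1)
    for pos in range(m - 1, -1, -1):
        candidate = min(Fraction(1), Fraction(m, pos + 1) * ps[order[pos]])
        running = min(running, candidate)
        q_sorted[pos] = running
    out: list[Fraction] = [Fraction(0)] * m
    for pos, idx in enumerate(order):
        out[idx] = q_sorted[pos]
    return out


def hwe_chi2_exact(n_hom_ref: int, n_het: int, n_hom_var: int) -> Fraction:
    """Pearson HWE chi-square as an exact rational (gene-counting p-hat)."""
    n = n_hom_ref + n_het + n_hom_var
    p = Fraction(2 * n_hom_ref + n_het, 2 * n)
    q = 1 - p
    expected = (p * p * n, 2 * p * q * n, q * q * n)
    chi2 = Fraction(0)
    for obs, exp in zip((n_hom_ref, n_het, n_hom_var), expected):
        if exp > 0:
            chi2 += (obs - exp) ** 2 / exp
    return chi2
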