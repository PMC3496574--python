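"""Hardy–Weinberg equilibrium testing for bi-allelic markers.

Given observed genotype counts (homozygote reference, heterozygote,
homozygote variant), the allele frequency p is estimated by gene counting,
expected counts follow the p², 2pq, q² proportions, and the deviation is
tested with Pearson's chi-square statistic on 1 degree of freedom (three
genotype classes, minus one constraint, minus one estimated frequency).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import chi2 as _chi2_dist


@dataclass(frozen=True)
class HweResult:
    """Outcome of one Hardy–Weinberg chi-square test."""

    n_hom_ref: int
    n_het: int
    n_hom_var: int
    p_allele: float
    q_allele: float
    expected: tuple[float, float, float]
    chi2: float
    df: int
    p_value: float
    alpha: float
    reject_equilibrium: bool
    monomorphic: bool = False

    def __str__(self) -> str:
        lines = [
            f"observed   hom_ref={self.n_hom_ref}  het={self.n_het}  hom_var={self.n_hom_var}",
            f"alleles    p={self.p_allele:.6g}  q={self.q_allele:.6g}",
            "expected   hom_ref={:.4f}  het={:.4f}  hom_var={:.4f}".format(*self.expected),
            f"chi2       {self.chi2:.6g}  (df={self.df})",
            f"p-value    {self.p_value:.6g}",
            f"alpha      {self.alpha:g}",
            f"decision   {'REJECT equilibrium' if self.reject_equilibrium else 'consistent with equilibrium'}"
            + ("  [monomorphic]" if self.monomorphic else ""),
        ]
        return "\n".join(lines)


def hwe_chi_square(
    n_hom_ref: int,
    n_het: int,
    n_hom_var: int,
    alpha: float = 0.05,
    yates: bool = False,
) -> HweResult:
    """Pearson chi-square test of Hardy–Weinberg equilibrium.

    Parameters are observed genotype COUNTS (not frequencies): the expected
    counts require the sample size n.  *yates* applies the continuity
    correction (off by default).  A monomorphic input (p = 0 or 1) has no
    testable deviation: chi2 = 0, p-value 1, flagged ``monomorphic``.
    """
    counts = (n_hom_ref, n_het, n_hom_var)
    for c in counts:
        if int(c) != c or c < 0:
            raise ValueError(f"genotype counts must be non-negative integers, got {c}")
    n = sum(int(c) for c in counts)
    if n < 1:
        raise ValueError("total genotype count must be at least 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")

    p = (2 * n_hom_ref + n_het) / (2 * n)
    q = 1.0 - p
    expected = (p * p * n, 2 * p * q * n, q * q * n)
    monomorphic = p in (0.0, 1.0)

    if monomorphic:
        chi2 = 0.0
        p_value = 1.0
    else:
        chi2 = 0.0
        for obs, exp in zip(counts, expected):
            if exp > 0:
                dev = abs(obs - exp)
                if yates:
                    dev = max(0.0, dev - 0.5)
                chi2 += dev * dev / exp
        p_value = float(_chi2_dist.sf(chi2, 1))

    return HweResult(
        n_hom_ref=int(n_hom_ref),
        n_het=int(n_het),
        n_hom_var=int(n_hom_var),
        p_allele=p,
        q_allele=q,
        expected=expected,
        chi2=chi2,
        df=1,
        p_value=p_value,
        alpha=alpha,
        reject_equilibrium=bool(p_value < alpha),
        monomorphic=monomorphic,
    )
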