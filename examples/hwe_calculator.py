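"""Hardy-Weinberg equilibrium check from observed genotype counts.

Two inputs: one exactly at equilibrium, one strongly deviating.
"""

from dmetkit import hwe_chi_square

print("-- counts (25, 50, 25): exact Hardy-Weinberg proportions at p = 0.5 --")
print(hwe_chi_square(25, 50, 25, alpha=0.05))
print()
print("-- counts (50, 20, 30): heterozygote deficit --")
print(hwe_chi_square(50, 20, 30, alpha=0.05))
print()
print(
    "The first marker matches its expected p^2/2pq/q^2 counts exactly, so\n"
    "chi2 = 0 and equilibrium is not rejected.  The second has far fewer\n"
    "heterozygotes than the 48 expected at p = 0.6 (chi2 ~ 34, df = 1),\n"
    "a strong equilibrium violation - in a real study a signal to check\n"
    "genotyping quality or population structure at that marker."
)
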