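"""Size an SSD population for marker-assisted forward breeding.

A breeder selects for two unlinked QTLs in fixed F5 lines and wants 100
lines homozygous-favourable at both, tolerating a 1% chance of falling
short.  The naive Mendelian calculation divides the requirement by the
genotype frequency; the binomial sizing controls the risk explicitly.
"""

from fractions import Fraction

from masplan import (
    GenerationSpec,
    SelectionMode,
    expected_positives,
    n_for_r,
    naive_mendelian_n,
    segregation_ratio,
)

P = segregation_ratio(GenerationSpec.selfing(5), SelectionMode.FIXED_ONLY)
print(f"Per-locus F5 fixation ratio P = {P} = {float(P)}")
print(f"Two-locus positive frequency P^2 = {float(P) ** 2:.4f}")

naive = naive_mendelian_n(Fraction(P), 2, 100)
print(f"Naive Mendelian estimate: {naive} plants"
      " (the mean just meets the target; ~50% chance of falling short)")

sizing = n_for_r(float(P), q=2, r=100, f=0.01)
print(f"Binomial sizing at 1% failure risk: {sizing}")
print(f"At the naive size the expected yield is "
      f"{expected_positives(naive, float(P), 2):.1f} positives; the binomial "
      f"size buys insurance against the sampling spread.")
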