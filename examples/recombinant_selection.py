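"""Size a BC-F1 population for recombinant selection.

To introgress a gene without linkage drag, the breeder needs plants
carrying the donor allele at the target locus but the recipient allele
at a flanking marker 1 cM away.  Each BC-F1 plant is heterozygous at
the target with probability 1/2, and carries the required crossover
with probability D = 0.01, so the effective frequency is P*D = 0.005.
"""

from masplan import n_recombinant

one = n_recombinant(0.5, d=0.01, q=1, r=1, f=0.05)
print(f"At least one recombinant, 5% risk: {one}")

two = n_recombinant(0.5, d=0.01, q=1, r=2, f=0.05)
print(f"At least two recombinants (insurance against plant loss): {two}")

f2 = n_recombinant(0.75, d=0.01, q=1, r=1, f=0.05)
print(f"Same search in an F2 (heterozygotes selectable, P = 0.75): {f2}")
print("Selfing needs fewer plants but costs two extra generations; "
      "recombinant selection during backcrossing saves that time.")
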