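# masplan

Quantitative planning for marker-assisted selection (MAS) in plant
breeding programs.

Breeders who select on diagnostic markers face the same question in
every campaign: *how many plants must I grow and genotype to recover
enough individuals with the genotype I want?* The textbook Mendelian
answer — divide the requirement by the genotype frequency — sizes for
the *mean* outcome and therefore falls short roughly half the time.
`masplan` replaces it with exact binomial sizing, and packages the
surrounding calculations a molecular breeding program needs: segregation
ratios across breeding generations, recombinant-selection sizing for
breaking linkage drag, Monte-Carlo validation, false-positive /
false-negative grading of candidate markers on germplasm panels, and
QTL value and deployment-strategy assessment.

## The model

An individual in the selection generation carries the desired genotype
at one target locus with probability *P* (the segregation ratio):
*P* = (1 − (½)^(t−1))/2 for a homozygous-favourable line in the F_t of a
single-seed-descent series (0.46875 in the F5), ¾ in an F2 when
heterozygotes are kept, ½ for a heterozygote in BC-F1 progeny, ½ for a
doubled haploid. With *Q* unlinked loci the per-individual probability
is *P^Q*; the number of positives in a population of size *n* is
Binomial(*n*, *P^Q*).

For one required positive, the smallest population with failure risk at
most *F* solves (1 − *P^Q*)^n ≤ *F*, i.e. *n*(1) = log F ⁄ log(1 − P^Q).
For *R* required positives, the failure probability is the binomial CDF
at *R* − 1, and `masplan` searches for the smallest *n* with
CDF(*R* − 1; *n*, *P^Q*) ≤ *F* by exact evaluation (incomplete beta, no
normal or Poisson approximation; an exact-rational evaluator is included
for auditing). For recombinant selection — recovering the donor allele
at the target but the recipient allele at a flanking marker *D* Morgans
away — the per-locus ratio deflates to *P·D*.

## A worked example

Recombinant selection during backcrossing, flanking marker at 1 cM,
wanting two recombinants as insurance against losing a plant
(`examples/recombinant_selection.py`):

```python
>>> from masplan import n_recombinant
>>> print(n_recombinant(0.5, d=0.01, q=1, r=2, f=0.05))
n = 947 (effective p = 0.005, achieved failure = 0.04998, expected positives = 4.74)
```

947 BC-F1 plants keep the chance of finding fewer than two usable
recombinants below 5%; on average the population contains 4.7 of them,
and growing fewer plants would push the failure risk over budget.
The same calculators back a small CLI:

```
$ masplan size --p 0.5 -Q 1 -R 10 -F 0.01       # line augmentation
33
$ masplan size-table --table 1                  # forward-breeding table as CSV
$ masplan qtl-strategy --frequency 0.9 --effect 35
MAS in forward breeding
```

The `examples/` directory holds one short narrative script per
capability: forward-breeding sizing, recombinant selection, two-stage
F2 enrichment, marker grading, Monte-Carlo validation, and QTL
deployment strategy.

## Layout

- `src/masplan/segregation.py` — genotype distributions per generation
  (exact rationals).
- `src/masplan/popsize.py` — sizing: closed form, binomial search,
  recombinant selection, two-stage plans, published tables.
- `src/masplan/simulate.py` — seeded Monte-Carlo validation.
- `src/masplan/markers.py` — FPR/FNR grading, ranking, cross-success
  prediction, QTL profiles.
- `src/masplan/panels.py` — panel CSV / minimal VCF I/O and the
  synthetic panel generator.
- `src/masplan/qtlvalue.py` — effect-size calculators and the
  deployment decision matrix.
- `src/masplan/cli.py` — the `masplan` command.

See `docs/methods.md` for the modelling assumptions, conventions and
limitations.
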