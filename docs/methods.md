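# Methods

## Genetic model

Every target locus is biallelic and starts heterozygous in the F1 of a
biparental cross; loci are unlinked and segregate independently. Three
derivation pathways are modelled.

**Selfing (single-seed descent).** One seed is advanced per plant per
generation, so a lineage is a Markov chain on {AA, Aa, aa}: homozygotes
are absorbing, and a heterozygote's descendant is AA, Aa, aa with
probabilities ¼, ½, ¼. After t − 1 rounds (generation F_t) the
heterozygous probability is (½)^(t−1) and each homozygous class holds
(1 − (½)^(t−1))/2 — 0.46875 in the F5, converging to ½. These
probabilities are kept as exact rationals (`fractions.Fraction`) inside
the package and converted to floats only at API boundaries, so values
like 15/32 and 31/48 survive downstream arithmetic unchanged.

**Backcrossing.** A donor-derived locus in BC-F1 progeny segregates 1:1
heterozygous : homozygous-recipient in every backcross generation. The
desired foreground genotype is the heterozygote; asking for a
favourable *homozygote* in BC-F1 returns probability 0 with a warning
rather than an exception, so that sizing over arbitrary inputs stays a
total function and the infeasibility surfaces as an explicit error at
the sizing step.

**Doubled haploids.** Each locus is fixed, favourable with probability
½; there are no heterozygotes.

### F2 enrichment

The two-stage strategy discards F2 plants homozygous-unfavourable at
any target locus (per-locus survival ¾, since heterozygotes are kept).
Survivors at one locus are ⅓ fixed-favourable and ⅔ heterozygous. The
enriched fixation ratio reported for a later generation F_t is

    ratio(t) = 1/3 + (2/3) · (1 − (1/2)^(t−1)) / 2 ,

i.e. the heterozygous survivors re-enter the inbreeding series and
their descendants carry the same number of segregating rounds (t − 1)
as the plain F_t label, so the enriched and unenriched ratios at a
given generation label are directly comparable like for like. At t = 5
this gives 31/48 ≈ 0.6458 against 15/32 = 0.46875 unenriched, with
limit ⅔. Under the alternative convention that counts only the three
rounds physically separating an F2 plant from an F5 descendant the
value is 5/8 = 0.625; both are consistent with the "about two-thirds"
folklore figure, and the package standardises on the comparable-label
convention throughout (analytic ratio, two-stage planning, and the
Monte-Carlo enrichment check use the same definition).

## Population sizing

With per-locus ratio P and Q unlinked loci, an individual is positive
with probability p = P^Q (deflated to Π P·D_i for recombinant
selection, see below). The count of positives in n individuals is
Binomial(n, p); the failure probability for a requirement of R is the
CDF at R − 1. The minimal size is the smallest n with failure ≤ F —
the boundary is inclusive, and the search is exponential bracketing
from a mean-based lower bound followed by bisection (the CDF is
strictly decreasing in n). For R = 1 the closed form
n(1) = ⌈log F / log(1 − p)⌉ is used, verified by direct evaluation at
n and n − 1 so the result is exactly minimal even when the logarithm
lands on an integer boundary.

CDF evaluation uses `scipy.stats.binom` (regularised incomplete beta,
accurate to double precision); no normal or Poisson approximation
appears anywhere in sizing. `failure_probability_exact` recomputes any
moderate-sized case in exact rational arithmetic (`math.comb` +
`Fraction`) and is used as the independent oracle in the test suite.
Published table values produced by other software occasionally differ
from the exact minimum by a few plants in either direction; this
package always reports the exact minimum and treats such published
values as upper bounds where they exceed it.

The *naive Mendelian* estimate round(R/p) (half away from zero) is
reported for comparison only: it sizes for the mean and under-delivers
roughly half the time. It is provably below the binomial sizing at the
failure risks used in practice (tested at F ∈ {0.01, 0.05, 0.1}), but
not at degenerate risks near 50%, where rounding can put it above the
exact requirement.

### Recombinant selection

To break linkage drag the breeder needs the donor allele at the target
locus and the recipient allele at a flanking marker D Morgans away.
The map distance enters the segregation ratio directly as the
recombination probability (1 cM → D = 0.01), a two-point model with
double recombinants ignored; no Haldane/Kosambi mapping-function
conversion is applied. The per-locus ratio becomes P·D and the sizing
machinery is otherwise unchanged, including the R ≥ 1 binomial search
that pure n(1) formulas cannot provide.

### Two-stage planning

The overall failure budget F is split evenly between the stages (no
published allocation exists; the split is a parameter and is echoed in
the plan output). Stage 2 sizes the fixed-generation selection with
the enriched per-locus ratio; stage 1 finds the F2 cohort large enough
that, with per-plant survival 0.75^Q, at least the stage-2 population
survives enrichment. Because the efficiency claim for two-stage
selection can be read against either genotyping effort or nursery
occupancy, the plan reports both: total genotyped samples
(n_F2 + n_fixed) and plant-generations (n_F2 + (t_fix − 2)·n_fixed,
versus (t_fix − 1)·n for single-stage). With one locus the second
genotyping pass makes two-stage strictly more expensive in samples; by
three loci it saves roughly half the plant-generations.

## Monte-Carlo validation

Populations are simulated from the per-locus distributions with
numpy's PCG64 generator seeded through a `SeedSequence`; identical
configuration and seed give identical results, and draws are consumed
in a fixed documented order (for parallel replication, spawn child
seeds). Selfing generations can alternatively be simulated through the
explicit SSD Markov chain (`chain=True`), which must and does agree
with the closed form within Monte-Carlo error. Replicate failure
frequencies use the fact that, with independent loci, the per-replicate
positive count is exactly Binomial(n, p); a per-individual sampling
mode exists for cross-checking the genotype sampler at small n.
Recombinant selection is simulated at the gamete level (recombination
indicator × strand choice), not by drawing the collapsed success
probability. Validation targets in the tests use 10^5 replicates and a
3-standard-error band.

## Marker grading

On a panel of lines with known QTL status, FPR is the fraction of
scored status-negative lines whose call designates them positive, FNR
the mirror image on status-positive lines. Denominators exclude
missing calls and unknown-status lines; the call rate (non-missing
fraction over *all* lines) is reported separately, so a marker cannot
hide inaccuracy behind missingness. Heterozygous calls count as
positive by default (codominant assays detect the favourable allele;
enrichment keeps heterozygotes) and the policy is switchable. An empty
scored class raises rather than returning 0/0. Ranking sorts by (FPR,
FNR, 1 − call rate) with lexicographic tie-break — false positives
waste resources on lines that never had the gene and can even promote a
false donor, so they dominate the ordering. Cross-success prediction
marks a donor × recipient cross workable iff the marker calls the donor
positive and the recipient negative; a missing call on either parent
counts as failure.

The synthetic panel generator inverts the grading: requested (FPR,
FNR, call rate) are realised *exactly* by seeded shuffles, refusing
requests that are not representable as k/m for the panel's line counts
(the error lists achievable values). Missing calls are allocated per
status class so the scored denominators stay whole.

Panel CSV is the canonical format (`line_id,role,qtl_status,<markers>`,
calls A/B/H/NA); the VCF reader is a deliberate minimal convenience —
GT fields only, favourable alleles designated per site through a
sidecar TSV, 1-based positions preserved in marker metadata.

## QTL value and deployment

PVE (r²) measures variance explained *within one mapping population*
and inflates in narrow materials, so two portable effect summaries are
provided: PVE × population variance, and the difference of genotypic
class means (plain arithmetic means; no outlier handling). Indirect
selection on a proxy trait attenuates by the proxy-target correlation
(0.20 × 0.65 = 13%).

The deployment decision matrix buckets favourable-allele frequency
(high > 80%, low < 5%, moderate between — both printed inequalities are
strict, so exact boundary values fall to the moderate bucket) against
effect size (major strictly above a 30% improvement) and returns the
recommended strategy list for each of the six cells, from "MAS in
forward breeding" alone (high frequency, major effect) to the full
deployment cascade for rare major genes.

## Problem sizes and limitations

Default test and validation sizes — tables to Q = 5, simulations at
10^5 replicates or individuals — run in seconds on a single core and
are the regime the method targets; the calculators themselves are
closed-form or logarithmic-time and handle any practical input.

Not modelled: linked multi-locus selfing dynamics beyond the single
target+flank pair, selection on polygenic background, recurrent-parent
genome recovery, multi-generation recurrent selection optimisation,
economic allocation of the failure budget, marker assay chemistry,
phasing or imputation. The synthetic panel generator emulates
validated biparental materials with known truth; it does not emulate
population structure, allele-frequency gradients or genotyping batch
effects, so passing grades on synthetic panels demonstrate correctness
of the accounting, not robustness of any particular marker in real
germplasm.
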