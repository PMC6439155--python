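"""Required population sizes for marker-assisted selection.

The planning problem: a population segregates for ``Q`` unlinked target
loci, each with per-locus probability ``P`` of the desired genotype
class, so one individual is a "positive" with probability ``P**Q``.  The
breeder needs at least ``R`` positives and accepts a failure risk ``F``
(the probability of recovering fewer than ``R``).  The number of
positives in a population of size ``n`` is Binomial(n, P**Q), so the
failure probability is the binomial CDF at ``R - 1`` and the required
size is the smallest ``n`` whose failure probability does not exceed
``F`` (inclusive boundary).

For ``R = 1`` this reduces to the closed form
``n(1) = log F / log(1 - P**Q)``.  For recombinant selection (breaking
linkage drag around an introgressed locus) the per-locus probability is
deflated by the map distance ``D`` in Morgans between the peak and the
flanking marker: the effective ratio is ``P * D`` per locus, so a
recombinant 1 cM away contributes ``D = 0.01``.

Binomial CDFs are evaluated with :func:`scipy.stats.binom` (regularised
incomplete beta, accurate to double precision; no normal or Poisson
approximation anywhere).  An exact-rational evaluator is provided for
auditing small problems.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import pandas as pd
from scipy.stats import binom

from .segregation import (
    GenerationSpec,
    SelectionMode,
    enriched_segregation_ratio,
    segregation_ratio,
)

__all__ = [
    "SelectionTarget",
    "SizingResult",
    "InfeasibleTargetError",
    "multi_locus_probability",
    "failure_probability",
    "failure_probability_exact",
    "n_at_least_one",
    "n_for_r",
    "n_recombinant",
    "solve",
    "naive_mendelian_n",
    "expected_positives",
    "TwoStagePlan",
    "two_stage_plan",
    "compare_strategies",
    "forward_breeding_table",
    "line_augmentation_table",
]

logger = logging.getLogger(__name__)


class InfeasibleTargetError(ValueError):
    """No finite population size can satisfy the target (effective p = 0)."""


def _validate(p, q: int, r: int = 1, f: float = 0.5) -> None:
    if not 0 <= p <= 1:
        raise ValueError(f"per-locus probability P={p} outside [0, 1]")
    if q < 1:
        raise ValueError(f"number of loci Q must be >= 1; got {q}")
    if r < 0:
        raise ValueError(f"required positives R must be >= 0; got {r}")
    if not 0 < f < 1:
        raise ValueError(f"failure risk F={f} outside (0, 1)")


@dataclass(frozen=True)
class SelectionTarget:
    """A sizing problem: per-locus probability ``p`` of the desired
    genotype, ``q`` unlinked loci, ``r`` required positives, acceptable
    failure risk ``f``, and optionally one flanking map distance (in
    Morgans) per locus for recombinant selection."""

    p: float | Fraction
    q: int = 1
    r: int = 1
    f: float = 0.05
    d: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        _validate(self.p, self.q, self.r, self.f)
        if self.r < 1:
            raise ValueError("a selection target needs R >= 1")
        if self.d is not None:
            d = tuple(float(x) for x in self.d)
            if len(d) == 1 and self.q > 1:
                d = d * self.q
            if len(d) != self.q:
                raise ValueError(
                    f"need one map distance per locus: got {len(d)} for Q={self.q}"
                )
            for x in d:
                if not 0 < x <= 1:
                    raise ValueError(f"map distance D={x} outside (0, 1] Morgans")
            object.__setattr__(self, "d", d)

    @classmethod
    def from_generation(
        cls,
        gen: GenerationSpec | str,
        mode: SelectionMode = SelectionMode.FIXED_ONLY,
        q: int = 1,
        r: int = 1,
        f: float = 0.05,
        d: Sequence[float] | None = None,
    ) -> "SelectionTarget":
        """Resolve the per-locus probability from a breeding generation."""
        if isinstance(gen, str):
            gen = GenerationSpec.parse(gen)
        p = segregation_ratio(gen, mode)
        return cls(p=p, q=q, r=r, f=f, d=tuple(d) if d is not None else None)

    @property
    def effective_p(self) -> float:
        """Per-individual probability of the full desired genotype."""
        if self.d is None:
            return float(self.p) ** self.q
        return math.prod(float(self.p) * di for di in self.d)


@dataclass(frozen=True)
class SizingResult:
    """A computed population size with its achieved failure probability
    and the expected number of positives at that size."""

    n: int
    achieved_failure: float
    expected_positives: float
    effective_p: float

    def __str__(self) -> str:
        return (
            f"n = {self.n} (effective p = {self.effective_p:.6g}, "
            f"achieved failure = {self.achieved_failure:.4g}, "
            f"expected positives = {self.expected_positives:.2f})"
        )


def multi_locus_probability(p, q: int):
    """Probability ``P**Q`` that one individual is positive at all Q
    unlinked loci.  Exact if ``p`` is a :class:`~fractions.Fraction`.

    >>> round(multi_locus_probability(0.46875, 2), 4)
    0.2197
    """
    _validate(p, q)
    return p**q


def failure_probability(n: int, p, q: int = 1, r: int = 1) -> float:
    """Probability of fewer than ``r`` positives in ``n`` individuals:
    BinomialCDF(r - 1; n, p**q)."""
    if n < 0:
        raise ValueError(f"population size must be >= 0; got {n}")
    _validate(p, q, r)
    if r == 0:
        return 0.0
    return float(binom.cdf(r - 1, n, float(multi_locus_probability(p, q))))


def failure_probability_exact(n: int, p, q: int = 1, r: int = 1) -> Fraction:
    """Exact-rational failure probability, for auditing.

    ``p`` must be exactly representable (Fraction, or a float whose
    binary value is intended, e.g. 0.5).  Cost grows with ``n * r``;
    intended for moderate problems (n up to a few thousand).
    """
    if n < 0:
        raise ValueError(f"population size must be >= 0; got {n}")
    _validate(p, q, r)
    pe = Fraction(p) ** q
    return sum(
        (Fraction(math.comb(n, k)) * pe**k * (1 - pe) ** (n - k) for k in range(r)),
        Fraction(0),
    )


def n_at_least_one(p, q: int = 1, f: float = 0.05) -> SizingResult:
    """Smallest n with ``(1 - p**q)**n <= f``: the closed-form sizing
    for at least one positive individual.

    Computed as the ceiling of ``log f / log(1 - p**q)`` and then
    verified by direct evaluation at ``n`` and ``n - 1`` so the returned
    size is exactly minimal under the inclusive boundary.

    >>> n_at_least_one(0.005, 1, 0.05).n
    598
    """
    _validate(p, q, 1, f)
    p_eff = float(multi_locus_probability(p, q))
    if p_eff == 0.0:
        raise InfeasibleTargetError(
            "effective probability is 0: no population size can succeed"
        )
    if p_eff == 1.0:
        n = 1
    else:
        miss = 1.0 - p_eff
        n = max(1, math.ceil(math.log(f) / math.log(miss)))
        while miss**n > f:  # guard against ceiling landing one short
            n += 1
        while n > 1 and miss ** (n - 1) <= f:
            n -= 1
    logger.info("n_at_least_one: effective p = %.10g -> n = %d", p_eff, n)
    return SizingResult(n, (1.0 - p_eff) ** n, n * p_eff, p_eff)


def _minimal_n(p_eff: float, r: int, f: float) -> int:
    """Smallest n with BinomialCDF(r-1; n, p_eff) <= f (exponential
    bracketing from a mean-based lower bound, then bisection; the CDF is
    strictly decreasing in n)."""
    if p_eff <= 0.0:
        raise InfeasibleTargetError(
            "effective probability is 0: no population size can succeed"
        )
    lo = max(r, 1)
    hi = max(lo, int(r / p_eff) or 1)
    while binom.cdf(r - 1, hi, p_eff) > f:
        lo = hi + 1
        hi *= 2
    # invariant: cdf(hi) <= f; cdf(lo - 1) > f (or lo is the floor r)
    while lo < hi:
        mid = (lo + hi) // 2
        if binom.cdf(r - 1, mid, p_eff) <= f:
            hi = mid
        else:
            lo = mid + 1
    return hi


def n_for_r(p, q: int = 1, r: int = 1, f: float = 0.05) -> SizingResult:
    """Minimal population size yielding at least ``r`` positives with
    failure probability at most ``f``.

    >>> n_for_r(0.5, q=1, r=10, f=0.01).n
    33
    """
    _validate(p, q, r, f)
    if r < 1:
        raise ValueError("R must be >= 1 for a sizing problem")
    p_eff = float(multi_locus_probability(p, q))
    n = _minimal_n(p_eff, r, f)
    logger.info(
        "n_for_r: per-locus P = %s, Q = %d -> effective p = %.10g; R = %d, F = %g -> n = %d",
        p, q, p_eff, r, f, n,
    )
    return SizingResult(n, failure_probability(n, p_eff, 1, r), n * p_eff, p_eff)


def n_recombinant(
    p, d: float | Sequence[float], q: int = 1, r: int = 1, f: float = 0.05
) -> SizingResult:
    """Sizing for recombinant selection: the per-locus ratio is deflated
    to ``p * d_i`` (``d_i`` in Morgans, so 1 cM -> 0.01), and the
    effective per-individual probability is the product over loci.

    >>> n_recombinant(0.5, 0.01, r=2, f=0.05).n
    947
    """
    ds = (float(d),) * q if isinstance(d, (int, float)) else tuple(float(x) for x in d)
    target = SelectionTarget(p=p, q=q, r=r, f=f, d=ds)
    return solve(target)


def solve(target: SelectionTarget) -> SizingResult:
    """Solve a :class:`SelectionTarget`, with or without map distances."""
    p_eff = target.effective_p
    if target.d is not None:
        logger.info(
            "recombinant selection: per-locus P = %s, D = %s Morgans -> effective p = %.10g",
            target.p, target.d, p_eff,
        )
    n = _minimal_n(p_eff, target.r, target.f)
    return SizingResult(
        n, failure_probability(n, p_eff, 1, target.r), n * p_eff, p_eff
    )


def naive_mendelian_n(p, q: int = 1, r: int = 1) -> int:
    """Mean-based estimate ``round(R / P**Q)`` (half away from zero).

    This is the textbook Mendelian calculation; it is a consistent
    *underestimate* of the size needed to recover R positives reliably
    (at that size the chance of falling short is roughly one half), and
    is provided for comparison and reporting only.

    >>> naive_mendelian_n(0.46875, 2, 100)
    455
    """
    _validate(p, q, max(r, 1))
    p_eff = multi_locus_probability(p, q)
    if p_eff == 0:
        raise InfeasibleTargetError("effective probability is 0")
    return math.floor(r / p_eff + 0.5)


def expected_positives(n: int, p, q: int = 1) -> float:
    """Mean number of positives in a population of size n: ``n * P**Q``.

    >>> expected_positives(145, 0.5, 4)
    9.0625
    """
    if n < 0:
        raise ValueError(f"population size must be >= 0; got {n}")
    _validate(p, q)
    return n * float(multi_locus_probability(p, q))


@dataclass(frozen=True)
class TwoStagePlan:
    """Sizes and cost metrics for two-stage (F2-enriched) selection.

    Stage 1 genotypes ``n_f2`` F2 plants and keeps those positive or
    heterozygous at every locus; stage 2 genotypes the ``n_fixed``
    surviving lineages in the fixed generation, where the per-locus
    ratio has risen to the enriched value.  Because the efficiency claim
    can be read against either genotyping effort or greenhouse
    occupancy, both metrics are reported, alongside the single-stage
    comparator.
    """

    q: int
    r: int
    f: float
    t_fix: int
    stage_risk: tuple[float, float]
    enriched_p: float
    n_f2: int
    n_fixed: int
    total_genotyped: int
    plant_generations: int
    single_stage_n: int
    single_stage_genotyped: int
    single_stage_plant_generations: int

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def two_stage_plan(
    q: int, r: int, f: float, t_fix: int = 5, risk_split: float = 0.5
) -> TwoStagePlan:
    """Plan a two-stage F2-enrichment selection against ``q`` loci.

    The overall failure risk ``f`` is split between the stages
    (``risk_split`` to the F2 stage, the rest to the fixed stage; an
    even split by default, reported so users can re-allocate).  Stage 2
    needs ``n_fixed`` lineages sized with the enriched per-locus ratio
    (31/48 at t_fix = 5); stage 1 must deliver at least ``n_fixed``
    all-locus survivors from ``n_f2`` F2 plants, each surviving with
    probability ``0.75**q``.

    Cost metrics: ``total_genotyped = n_f2 + n_fixed`` samples, and
    ``plant_generations = n_f2 + (t_fix - 2) * n_fixed`` plant-rounds in
    the SSD nursery (the F2 cohort once, then only survivors onward).
    """
    _validate(1.0, q, r, f)
    if not 0 < risk_split < 1:
        raise ValueError("risk_split must be in (0, 1)")
    f_f2 = f * risk_split
    f_fix = f * (1.0 - risk_split)
    p_enriched = enriched_segregation_ratio(t_fix)
    n_fixed = n_for_r(float(p_enriched), q, r, f_fix).n
    n_f2 = n_for_r(0.75, q, n_fixed, f_f2).n
    p_single = segregation_ratio(
        GenerationSpec.selfing(t_fix), SelectionMode.FIXED_ONLY
    )
    n_single = n_for_r(float(p_single), q, r, f).n
    return TwoStagePlan(
        q=q,
        r=r,
        f=f,
        t_fix=t_fix,
        stage_risk=(f_f2, f_fix),
        enriched_p=float(p_enriched),
        n_f2=n_f2,
        n_fixed=n_fixed,
        total_genotyped=n_f2 + n_fixed,
        plant_generations=n_f2 + (t_fix - 2) * n_fixed,
        single_stage_n=n_single,
        single_stage_genotyped=n_single,
        single_stage_plant_generations=(t_fix - 1) * n_single,
    )


def compare_strategies(q: int, r: int, f: float, t_fix: int = 5) -> pd.DataFrame:
    """Tabulate single-stage fixed-generation selection, two-stage
    F2 enrichment, and F2-only (heterozygotes included) selection.

    Returns a DataFrame indexed by strategy with the population size(s)
    genotyped at each stage, total genotyped samples and SSD
    plant-generations.  The F2-only row sizes selection at the F2 with
    the include-heterozygote ratio 0.75; its positives are enriched, not
    fixed, so it is a comparator rather than a substitute.
    """
    plan = two_stage_plan(q, r, f, t_fix)
    p_f2 = segregation_ratio(GenerationSpec.selfing(2), SelectionMode.INCLUDE_HET)
    n_f2_only = n_for_r(float(p_f2), q, r, f).n
    rows = {
        "single_stage_fixed": {
            "n_stage1": plan.single_stage_n,
            "n_stage2": 0,
            "total_genotyped": plan.single_stage_genotyped,
            "plant_generations": plan.single_stage_plant_generations,
        },
        "two_stage": {
            "n_stage1": plan.n_f2,
            "n_stage2": plan.n_fixed,
            "total_genotyped": plan.total_genotyped,
            "plant_generations": plan.plant_generations,
        },
        "f2_only_include_het": {
            "n_stage1": n_f2_only,
            "n_stage2": 0,
            "total_genotyped": n_f2_only,
            "plant_generations": n_f2_only,
        },
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def _size_table(p, r_values: Sequence[int], f: float, q_max: int) -> pd.DataFrame:
    data = {
        r: [n_for_r(p, q, r, f).n for q in range(1, q_max + 1)] for r in r_values
    }
    table = pd.DataFrame(data, index=pd.Index(range(1, q_max + 1), name="Q"))
    table.columns.name = "R"
    return table


def forward_breeding_table(
    f: float = 0.01, q_max: int = 5, r_values: Sequence[int] = (50, 100, 200)
) -> pd.DataFrame:
    """Required SSD population sizes for forward breeding: fixed-line
    selection in the F5 (per-locus P = 15/32), failure risk ``f``,
    Q = 1..q_max loci by R required fixed-positive lines."""
    return _size_table(Fraction(15, 32), r_values, f, q_max)


def line_augmentation_table(
    f: float = 0.01, q_max: int = 5, r_values: Sequence[int] = (5, 10, 20)
) -> pd.DataFrame:
    """Required BC-F1 population sizes for line augmentation:
    foreground selection for heterozygotes (per-locus P = 1/2)."""
    return _size_table(Fraction(1, 2), r_values, f, q_max)
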