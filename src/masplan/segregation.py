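"""Single-locus genotype distributions across breeding generations.

Every target locus is assumed to start heterozygous in the F1 of a
biparental cross, and loci are unlinked and independent.  Three pathways
are modelled:

* ``selfing`` — single-seed descent (SSD / rapid generation advance):
  the heterozygous fraction halves every generation, so in the F_t
  generation ``p_het = (1/2)**(t-1)`` and the remainder splits evenly
  between the two homozygous classes.
* ``backcross`` — foreground selection in BC-F1 progeny: every
  donor-derived target locus segregates 1:1 heterozygous to
  homozygous-recipient; no favourable homozygotes exist.
* ``doubled_haploid`` — each locus is fixed, favourable with
  probability 1/2.

All probabilities are exact rationals (`fractions.Fraction`) internally;
convert with :meth:`GenotypeDistribution.as_floats` or ``float()`` at the
boundary.  This keeps quantities such as the F5 fixation ratio 15/32 =
0.46875 exact through downstream arithmetic.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from enum import Enum
from fractions import Fraction

__all__ = [
    "Pathway",
    "SelectionMode",
    "GenerationSpec",
    "GenotypeDistribution",
    "locus_distribution",
    "segregation_ratio",
    "enriched_segregation_ratio",
]


class Pathway(str, Enum):
    """Breeding pathway through which a population was derived."""

    SELFING = "selfing"
    BACKCROSS = "backcross"
    DOUBLED_HAPLOID = "doubled_haploid"


class SelectionMode(str, Enum):
    """Which genotype classes count as selectable positives.

    ``FIXED_ONLY`` selects favourable homozygotes; ``INCLUDE_HET``
    additionally keeps heterozygotes (the natural mode for codominant
    markers, for F2 enrichment, and for BC-F1 foreground selection where
    the heterozygote *is* the desired class).
    """

    FIXED_ONLY = "fixed_only"
    INCLUDE_HET = "include_het"


@dataclass(frozen=True)
class GenerationSpec:
    """A breeding generation: pathway plus generation index.

    For selfing the index is the F-number (``t >= 2``; F_t is reached
    from the F1 by ``t - 1`` rounds of selfing).  For backcrossing it is
    the BC generation number (genotypes are assessed in BC-F1 progeny,
    where the segregation ratio is the same for every BC generation).
    Doubled haploids ignore the index.
    """

    pathway: Pathway
    index: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "pathway", Pathway(self.pathway))
        if self.pathway is Pathway.SELFING and self.index < 2:
            raise ValueError(
                f"selfing generations start at F2; got F{self.index}"
            )
        if self.pathway is Pathway.BACKCROSS and self.index < 1:
            raise ValueError(
                f"backcross generation must be >= 1; got BC{self.index}"
            )

    @classmethod
    def selfing(cls, t: int) -> "GenerationSpec":
        """The F_t generation of a selfing (SSD) series, t >= 2."""
        return cls(Pathway.SELFING, t)

    @classmethod
    def backcross(cls, generation: int = 1) -> "GenerationSpec":
        """BC_generation, genotype assessed in BC-F1 progeny."""
        return cls(Pathway.BACKCROSS, generation)

    @classmethod
    def doubled_haploid(cls) -> "GenerationSpec":
        return cls(Pathway.DOUBLED_HAPLOID, 0)

    @classmethod
    def parse(cls, text: str) -> "GenerationSpec":
        """Parse ``"F5"``, ``"BC1"`` / ``"BC2F1"``, or ``"DH"``."""
        s = text.strip().upper()
        if s == "DH":
            return cls.doubled_haploid()
        m = re.fullmatch(r"F(\d+)", s)
        if m:
            return cls.selfing(int(m.group(1)))
        m = re.fullmatch(r"BC(\d+)(?:F1)?", s)
        if m:
            return cls.backcross(int(m.group(1)))
        raise ValueError(
            f"cannot parse generation {text!r}; expected e.g. 'F5', 'BC1' or 'DH'"
        )

    def __str__(self) -> str:
        if self.pathway is Pathway.SELFING:
            return f"F{self.index}"
        if self.pathway is Pathway.BACKCROSS:
            return f"BC{self.index}-F1"
        return "DH"


@dataclass(frozen=True)
class GenotypeDistribution:
    """Exact per-locus genotype probabilities (favourable homozygote,
    heterozygote, unfavourable homozygote); they sum to 1."""

    p_hom_fav: Fraction
    p_het: Fraction
    p_hom_unfav: Fraction

    def __post_init__(self) -> None:
        for p in (self.p_hom_fav, self.p_het, self.p_hom_unfav):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.p_hom_fav + self.p_het + self.p_hom_unfav != 1:
            raise ValueError("genotype probabilities must sum to 1 exactly")

    def as_floats(self) -> tuple[float, float, float]:
        return (float(self.p_hom_fav), float(self.p_het), float(self.p_hom_unfav))


def _selfing_het(t: int) -> Fraction:
    # t - 1 rounds of selfing from a heterozygous F1
    return Fraction(1, 2 ** (t - 1))


def locus_distribution(gen: GenerationSpec) -> GenotypeDistribution:
    """Exact single-locus genotype distribution for a generation.

    Examples
    --------
    >>> locus_distribution(GenerationSpec.selfing(2)).as_floats()
    (0.25, 0.5, 0.25)
    >>> float(locus_distribution(GenerationSpec.selfing(5)).p_hom_fav)
    0.46875
    """
    if gen.pathway is Pathway.SELFING:
        het = _selfing_het(gen.index)
        hom = (1 - het) / 2
        return GenotypeDistribution(hom, het, hom)
    if gen.pathway is Pathway.BACKCROSS:
        return GenotypeDistribution(Fraction(0), Fraction(1, 2), Fraction(1, 2))
    return GenotypeDistribution(Fraction(1, 2), Fraction(0), Fraction(1, 2))


def segregation_ratio(gen: GenerationSpec, mode: SelectionMode) -> Fraction:
    """Probability P that one individual carries the desired genotype
    class at a single locus.

    For backcross populations the desired foreground genotype is the
    heterozygote, so ``INCLUDE_HET`` returns 1/2 while ``FIXED_ONLY``
    returns 0 (with a warning): no favourable homozygote can occur in
    BC-F1 progeny.  Returning 0 rather than raising keeps downstream
    sizing total — an infeasible probability is reported there.
    """
    mode = SelectionMode(mode)
    dist = locus_distribution(gen)
    if mode is SelectionMode.FIXED_ONLY:
        if gen.pathway is Pathway.BACKCROSS:
            warnings.warn(
                "BC-F1 progeny contain no favourable homozygotes; "
                "fixed-only selection probability is 0",
                stacklevel=2,
            )
        return dist.p_hom_fav
    return dist.p_hom_fav + dist.p_het


def enriched_segregation_ratio(t: int = 5) -> Fraction:
    """Per-locus fixation ratio in generation F_t after F2 enrichment.

    In the two-stage strategy, progeny that are homozygous-unfavourable
    at the locus are discarded at the F2; the survivors are 1/3
    favourable homozygotes (already fixed) and 2/3 heterozygotes.  The
    heterozygous survivors re-enter the inbreeding series, and their
    descendants are advanced through the same number of segregating
    rounds (``t - 1``) carried by the F_t label of the plain series, so
    that the enriched and unenriched ratios at a given generation label
    are directly comparable:

    ``ratio(t) = 1/3 + 2/3 * (1 - (1/2)**(t-1)) / 2``

    At t = 5 this is 31/48 ~= 0.6458, against 15/32 = 0.46875 without
    enrichment; as t grows it converges to 2/3 (all residual
    heterozygotes resolve half-and-half).

    >>> enriched_segregation_ratio(5)
    Fraction(31, 48)
    """
    if t < 3:
        raise ValueError(
            f"enriched ratio is defined for generations after the F2 (t >= 3); got t={t}"
        )
    hom_given_het = (1 - _selfing_het(t)) / 2
    return Fraction(1, 3) + Fraction(2, 3) * hom_given_het
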