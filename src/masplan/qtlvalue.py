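"""QTL effect-size assessment and deployment-strategy choice.

The percentage of variance explained (PVE, r^2) reported by mapping
software measures variation *within one mapping population* and can be
inflated in narrow materials; the absolute effect proxy
``PVE x population variance`` and the genotypic-class mean difference
are the more portable summaries.  When the mapped trait is only a proxy
for the breeding target, expected improvement attenuates by the
proxy-target correlation: a QTL with PVE 0.20 on a proxy correlated at
0.65 with the target delivers only 0.20 x 0.65 = 13% improvement.

The deployment decision depends on where the favourable allele already
stands in the elite program (frequency) and how much it is worth
(effect size); :func:`deployment_strategy` encodes that decision matrix.
"""

from __future__ import annotations

from enum import Enum
from statistics import fmean
from typing import Sequence

__all__ = [
    "EffectClass",
    "FrequencyClass",
    "absolute_effect_from_pve",
    "class_mean_effect",
    "indirect_selection_attenuation",
    "classify_effect",
    "classify_frequency",
    "deployment_strategy",
    "STRATEGY_MATRIX",
]


class EffectClass(str, Enum):
    MINOR = "minor"
    MAJOR = "major"


class FrequencyClass(str, Enum):
    LOW = "low"  # < 5% of elite lines carry the favourable allele
    MODERATE = "moderate"
    HIGH = "high"  # > 80%


# Bucket boundaries follow the printed strict inequalities: high only
# above 0.80, low only below 0.05, major only above a 30% improvement;
# exact boundary values fall to the middle/minor bucket.
HIGH_FREQUENCY = 0.80
LOW_FREQUENCY = 0.05
MAJOR_EFFECT_PERCENT = 30.0

STRATEGY_MATRIX: dict[tuple[FrequencyClass, EffectClass], tuple[str, ...]] = {
    (FrequencyClass.HIGH, EffectClass.MAJOR): ("MAS in forward breeding",),
    (FrequencyClass.HIGH, EffectClass.MINOR): ("Genomic selection",),
    (FrequencyClass.MODERATE, EffectClass.MAJOR): (
        "Haplotype embedding",
        "MAS in forward breeding",
    ),
    (FrequencyClass.MODERATE, EffectClass.MINOR): (
        "Pyramiding",
        "Trait introgression",
        "Genomic selection",
    ),
    (FrequencyClass.LOW, EffectClass.MAJOR): (
        "QTL deployment",
        "Haplotype embedding",
        "Pyramiding",
        "Trait introgression",
        "Genomic selection",
    ),
    (FrequencyClass.LOW, EffectClass.MINOR): (
        "QTL deployment",
        "Pyramiding",
        "Trait introgression",
        "Genomic selection",
    ),
}


def absolute_effect_from_pve(pve: float, population_variance: float) -> float:
    """Absolute-effect proxy: PVE x population trait variance
    (trait units squared)."""
    if not 0 <= pve <= 1:
        raise ValueError(f"PVE {pve} outside [0, 1]")
    if population_variance < 0:
        raise ValueError("population variance must be >= 0")
    return pve * population_variance


def class_mean_effect(
    favourable: Sequence[float], unfavourable: Sequence[float]
) -> float:
    """Mean trait difference between favourable- and unfavourable-
    homozygote classes (arithmetic means, no outlier handling).  For
    near-isogenic materials this is the mean difference from the
    recipient parent."""
    if not favourable or not unfavourable:
        raise ValueError("both genotypic classes need at least one observation")
    return fmean(favourable) - fmean(unfavourable)


def indirect_selection_attenuation(
    pve_on_proxy: float, proxy_trait_correlation: float
) -> float:
    """Expected proportional improvement on the target trait when
    selecting on a proxy: PVE(proxy) x corr(proxy, target).

    >>> indirect_selection_attenuation(0.20, 0.65)
    0.13
    """
    if not 0 <= pve_on_proxy <= 1:
        raise ValueError(f"PVE {pve_on_proxy} outside [0, 1]")
    if not -1 <= proxy_trait_correlation <= 1:
        raise ValueError(
            f"correlation {proxy_trait_correlation} outside [-1, 1]"
        )
    return pve_on_proxy * proxy_trait_correlation


def classify_effect(effect: "EffectClass | str | float") -> EffectClass:
    """Classify an effect as minor/major.

    Accepts the class itself, its name, or a numeric percentage
    improvement (major strictly above 30%; exactly 30% is minor).
    """
    if isinstance(effect, EffectClass):
        return effect
    if isinstance(effect, str):
        return EffectClass(effect.lower())
    return (
        EffectClass.MAJOR if float(effect) > MAJOR_EFFECT_PERCENT else EffectClass.MINOR
    )


def classify_frequency(frequency: float) -> FrequencyClass:
    """Bucket a favourable-allele frequency (proportion in [0, 1])."""
    if not 0 <= frequency <= 1:
        raise ValueError(f"frequency {frequency} outside [0, 1]")
    if frequency > HIGH_FREQUENCY:
        return FrequencyClass.HIGH
    if frequency < LOW_FREQUENCY:
        return FrequencyClass.LOW
    return FrequencyClass.MODERATE


def deployment_strategy(
    frequency: float, effect: "EffectClass | str | float"
) -> tuple[str, ...]:
    """Ordered deployment strategies for a QTL given its frequency in
    the elite program and its effect size.

    >>> deployment_strategy(0.90, "major")
    ('MAS in forward breeding',)
    """
    return STRATEGY_MATRIX[(classify_frequency(frequency), classify_effect(effect))]
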