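"""Monte-Carlo simulation of breeding populations.

Empirical cross-checks for the analytic segregation ratios and failure
probabilities: populations are drawn individual by individual from the
per-locus genotype distributions (or through the explicit single-seed-
descent Markov chain), and replicate failure frequencies are compared
with the exact binomial CDF.

Randomness comes from numpy's PCG64 generator seeded through a
``SeedSequence``; a call with the same configuration and seed consumes
draws in a fixed order and returns identical results.  For parallel
replication, spawn child seeds with
``np.random.SeedSequence(seed).spawn(k)`` and run one call per child.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping

import numpy as np

from .segregation import (
    GenerationSpec,
    Pathway,
    SelectionMode,
    locus_distribution,
    segregation_ratio,
)

__all__ = [
    "SimulationConfig",
    "PopulationSummary",
    "FailureEstimate",
    "RecombinantEstimate",
    "simulate_population",
    "empirical_failure",
    "simulate_recombinant_selection",
    "simulate_enrichment",
]

GENOTYPES = ("hom_fav", "het", "hom_unfav")  # integer codes 0, 1, 2


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration for one simulation experiment.

    ``recombination`` is the recombination fraction between a target
    locus and its flanking marker (used only by
    :func:`simulate_recombinant_selection`).  ``chain=True`` simulates
    selfing generations through the explicit per-generation Markov chain
    instead of drawing from the closed-form distribution.
    """

    gen: GenerationSpec
    n: int
    q: int = 1
    reps: int = 1
    seed: int = 0
    recombination: float | None = None
    chain: bool = False

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError(f"population size must be >= 0; got {self.n}")
        if self.q < 1:
            raise ValueError(f"loci count must be >= 1; got {self.q}")
        if self.reps < 1:
            raise ValueError(f"replicates must be >= 1; got {self.reps}")
        if self.recombination is not None and not 0 <= self.recombination <= 0.5:
            raise ValueError(
                f"recombination fraction {self.recombination} outside [0, 0.5]"
            )


def _rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))


def _draw_locus(rng: np.random.Generator, gen: GenerationSpec, size: int,
                chain: bool) -> np.ndarray:
    """Genotype codes for `size` independent individuals at one locus."""
    if chain and gen.pathway is Pathway.SELFING:
        return _self_chain(rng, np.ones(size, dtype=np.int8), gen.index - 1)
    probs = [float(p) for p in locus_distribution(gen).as_floats()]
    return rng.choice(3, size=size, p=probs).astype(np.int8)


def _self_chain(rng: np.random.Generator, state: np.ndarray, rounds: int) -> np.ndarray:
    """Advance heterozygous-coded individuals through `rounds` of
    single-seed descent; homozygotes are absorbing."""
    for _ in range(rounds):
        het = state == 1
        k = int(het.sum())
        if k == 0:
            break
        u = rng.random(k)
        nxt = np.where(u < 0.25, 0, np.where(u < 0.75, 1, 2)).astype(np.int8)
        state = state.copy()
        state[het] = nxt
    return state


@dataclass(frozen=True)
class PopulationSummary:
    """Genotype counts for one simulated population."""

    n: int
    q: int
    counts: Mapping[tuple[str, ...], int]

    def locus_frequency(self, locus: int, genotype: str) -> float:
        """Marginal frequency of `genotype` at `locus` (0-based)."""
        if self.n == 0:
            return float("nan")
        total = sum(
            c for cls, c in self.counts.items() if cls[locus] == genotype
        )
        return total / self.n

    def count_positive(self, mode: SelectionMode) -> int:
        """Individuals in the desired class at every locus."""
        mode = SelectionMode(mode)
        wanted = (
            {"hom_fav"} if mode is SelectionMode.FIXED_ONLY else {"hom_fav", "het"}
        )
        return sum(
            c for cls, c in self.counts.items() if all(g in wanted for g in cls)
        )


def simulate_population(cfg: SimulationConfig) -> PopulationSummary:
    """Draw one population of ``cfg.n`` individuals with ``cfg.q``
    independent loci and tally the multi-locus genotype classes.

    Deterministic for a fixed seed.  With ``cfg.chain`` set and a
    selfing generation, each individual is advanced through the
    explicit F1 -> F_t single-seed-descent chain rather than sampled
    from the closed-form distribution — a self-consistency check of the
    closed form.
    """
    rng = _rng(cfg.seed)
    if cfg.n == 0:
        return PopulationSummary(0, cfg.q, {})
    geno = np.empty((cfg.n, cfg.q), dtype=np.int8)
    for j in range(cfg.q):
        geno[:, j] = _draw_locus(rng, cfg.gen, cfg.n, cfg.chain)
    classes, counts = np.unique(geno, axis=0, return_counts=True)
    tally = {
        tuple(GENOTYPES[g] for g in row): int(c)
        for row, c in zip(classes, counts)
    }
    return PopulationSummary(cfg.n, cfg.q, tally)


@dataclass(frozen=True)
class FailureEstimate:
    """Empirical failure frequency with its binomial standard error."""

    estimate: float
    se: float
    reps: int
    n: int
    r: int
    effective_p: float


def empirical_failure(
    cfg: SimulationConfig,
    r: int,
    mode: SelectionMode = SelectionMode.FIXED_ONLY,
    p: float | Fraction | None = None,
    per_individual: bool = False,
) -> FailureEstimate:
    """Fraction of replicate populations with fewer than ``r``
    individuals positive at all ``q`` loci.

    The per-locus probability is taken from ``p`` if given, otherwise
    resolved from ``cfg.gen`` and ``mode``.  Since loci are independent,
    each individual is positive with probability ``p**q`` and the
    per-replicate positive count is an exact Binomial(n, p**q) draw;
    by default the count is sampled directly, which is the same
    stochastic experiment at a fraction of the cost.  Set
    ``per_individual=True`` to draw each genotype explicitly (slow;
    useful at small n as an extra check of the genotype sampler).
    """
    if r < 0:
        raise ValueError(f"required positives must be >= 0; got {r}")
    rng = _rng(cfg.seed)
    if p is None:
        p = segregation_ratio(cfg.gen, mode)
    p_eff = float(p) ** cfg.q
    if r == 0:
        return FailureEstimate(0.0, 0.0, cfg.reps, cfg.n, r, p_eff)
    if per_individual:
        positives = np.empty(cfg.reps, dtype=np.int64)
        wanted_max = 0 if SelectionMode(mode) is SelectionMode.FIXED_ONLY else 1
        for i in range(cfg.reps):
            geno = np.empty((cfg.n, cfg.q), dtype=np.int8)
            for j in range(cfg.q):
                geno[:, j] = _draw_locus(rng, cfg.gen, cfg.n, cfg.chain)
            positives[i] = int((geno <= wanted_max).all(axis=1).sum())
    else:
        positives = rng.binomial(cfg.n, p_eff, size=cfg.reps)
    est = float(np.mean(positives < r))
    se = float(np.sqrt(est * (1.0 - est) / cfg.reps))
    return FailureEstimate(est, se, cfg.reps, cfg.n, r, p_eff)


@dataclass(frozen=True)
class RecombinantEstimate:
    frequency: float
    se: float
    n_gametes: int


def simulate_recombinant_selection(cfg: SimulationConfig) -> RecombinantEstimate:
    """Empirical frequency of the desired recombinant class in BC-F1.

    The F1 carries the donor allele at the target locus and at the
    flanking marker in coupling phase.  Each BC-F1 individual receives
    one F1 gamete: with probability ``r`` (the recombination fraction,
    ``cfg.recombination``) the gamete is a recombinant, and
    independently each of the two strands is transmitted with
    probability 1/2.  A success is a gamete carrying the donor allele
    at the target but the recipient allele at the flank — frequency
    ``r / 2``, matching the deflated segregation ratio P*D with P = 1/2
    and D = r.  Double recombination is outside this two-point model.
    """
    if cfg.recombination is None:
        raise ValueError("cfg.recombination is required for recombinant simulation")
    rng = _rng(cfg.seed)
    total = cfg.n * cfg.reps
    if total == 0:
        return RecombinantEstimate(float("nan"), float("nan"), 0)
    successes = 0
    chunk = 5_000_000
    for start in range(0, total, chunk):
        m = min(chunk, total - start)
        recombinant = rng.random(m) < cfg.recombination
        donor_at_target = rng.random(m) < 0.5
        successes += int(np.sum(recombinant & donor_at_target))
    freq = successes / total
    se = float(np.sqrt(max(freq * (1 - freq), 0.0) / total))
    return RecombinantEstimate(freq, se, total)


def simulate_enrichment(t: int = 5, n: int = 100_000, seed: int = 0) -> float:
    """Empirical favourable-homozygote fraction in generation F_t after
    F2 enrichment at a single locus.

    F2 individuals are drawn 1:2:1 and the homozygous-unfavourable ones
    discarded; survivors (1/3 fixed favourable, 2/3 heterozygous) are
    advanced by single-seed descent, with the heterozygous lineages
    carried through ``t - 1`` segregating rounds — the same label
    convention as :func:`masplan.segregation.enriched_segregation_ratio`,
    whose exact value (31/48 at t = 5) this estimate converges to.
    """
    if t < 3:
        raise ValueError(f"enrichment is assessed after the F2 (t >= 3); got t={t}")
    if n < 1:
        raise ValueError(f"need at least one lineage; got n={n}")
    rng = _rng(seed)
    kept = np.where(rng.random(n) < 1.0 / 3.0, 0, 1).astype(np.int8)
    final = _self_chain(rng, kept, t - 1)
    return float(np.mean(final == 0))
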