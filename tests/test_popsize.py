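"""Population sizing: exact binomial search, closed forms, plans."""

import math
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from masplan.popsize import (
    InfeasibleTargetError,
    SelectionTarget,
    compare_strategies,
    expected_positives,
    failure_probability,
    failure_probability_exact,
    forward_breeding_table,
    line_augmentation_table,
    multi_locus_probability,
    n_at_least_one,
    n_for_r,
    n_recombinant,
    naive_mendelian_n,
    solve,
    two_stage_plan,
)


def exact_cdf(n: int, p: Fraction, r: int) -> Fraction:
    """Independent oracle: plain exact binomial CDF at r - 1."""
    return sum(
        Fraction(math.comb(n, k)) * p**k * (1 - p) ** (n - k) for k in range(r)
    )


def minimal_n_scan(p: Fraction, r: int, f: Fraction) -> int:
    """Independent oracle: linear scan for the smallest passing n."""
    n = r
    while exact_cdf(n, p, r) > f:
        n += 1
    return n


class TestMultiLocusProbability:
    def test_paper_rounding_of_two_locus_f5(self):
        assert round(multi_locus_probability(0.46875, 2), 4) == 0.2197

    def test_identity_and_powers(self):
        assert multi_locus_probability(0.37, 1) == 0.37
        assert multi_locus_probability(0.5, 4) == 0.0625
        assert multi_locus_probability(Fraction(15, 32), 2) == Fraction(225, 1024)


class TestFailureProbability:
    @pytest.mark.parametrize(
        "n, p, q, r, expected",
        [
            (32, Fraction(1, 2), 1, 10, Fraction(43081973, 2**32)),
            (33, Fraction(1, 2), 1, 10, Fraction(58115146, 2**33)),
            (145, Fraction(1, 2), 4, 5, None),  # checked against oracle below
        ],
    )
    def test_matches_exact_rational_oracle(self, n, p, q, r, expected):
        oracle = exact_cdf(n, p**q, r)
        if expected is not None:
            assert oracle == expected
        assert failure_probability(n, p, q, r) == pytest.approx(float(oracle), rel=1e-12)
        assert failure_probability_exact(n, p, q, r) == oracle

    def test_four_locus_bc_example(self):
        assert failure_probability(145, 0.5, 4, 5) == pytest.approx(0.0477, abs=5e-5)

    def test_r1_closed_form(self):
        for n, p in [(10, 0.3), (598, 0.005), (57, 0.5)]:
            assert failure_probability(n, p, 1, 1) == pytest.approx(
                (1 - p) ** n, rel=1e-12
            )

    def test_r0_and_empty_population(self):
        assert failure_probability(100, 0.5, 1, 0) == 0.0
        assert failure_probability(0, 0.5, 1, 1) == 1.0

    @given(
        n=st.integers(1, 300),
        p=st.fractions(Fraction(1, 100), Fraction(99, 100), max_denominator=100),
        r=st.integers(1, 10),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotone_decreasing_in_n_increasing_in_r(self, n, p, r):
        fp = float(p)
        assert failure_probability(n + 1, fp, 1, r) <= failure_probability(n, fp, 1, r)
        assert failure_probability(n, fp, 1, r + 1) >= failure_probability(n, fp, 1, r)


class TestAtLeastOne:
    @pytest.mark.parametrize(
        "p, q, f, expected",
        [
            (0.005, 1, 0.05, 598),  # BC recombinant at 1 cM
            (0.0075, 1, 0.05, 398),  # F2 include-het recombinant at 1 cM
            (0.46875, 1, 0.01, 8),
            (1.0, 1, 0.05, 1),
        ],
    )
    def test_known_sizes(self, p, q, f, expected):
        result = n_at_least_one(p, q, f)
        assert result.n == expected
        assert result.achieved_failure <= f
        if result.n > 1:
            assert (1 - result.effective_p) ** (result.n - 1) > f

    def test_infeasible_probability(self):
        with pytest.raises(InfeasibleTargetError):
            n_at_least_one(0.0, 1, 0.05)


class TestNForR:
    @pytest.mark.parametrize(
        "p, q, r, f, expected",
        [
            (0.5, 1, 10, 0.01, 33),  # line augmentation, 10 het-positives
            (0.005, 1, 2, 0.05, 947),  # recombinant selection worked example
            (0.5, 4, 5, 0.05, 144),
            (0.46875, 2, 100, 0.01, 555),
        ],
    )
    def test_known_sizes(self, p, q, r, f, expected):
        assert n_for_r(p, q, r, f).n == expected

    def test_minimality_against_scan_oracle(self):
        for p, r, f in [
            (Fraction(1, 2), 10, Fraction(1, 100)),
            (Fraction(15, 32), 5, Fraction(1, 20)),
            (Fraction(1, 16), 5, Fraction(1, 20)),
            (Fraction(3, 4), 7, Fraction(1, 10)),
        ]:
            expected = minimal_n_scan(p, r, f)
            assert n_for_r(float(p), 1, r, float(f)).n == expected

    def test_result_brackets_risk(self):
        res = n_for_r(0.3, 2, 8, 0.02)
        assert res.achieved_failure <= 0.02
        assert failure_probability(res.n - 1, 0.3, 2, 8) > 0.02

    @given(
        p=st.floats(0.05, 0.95),
        q=st.integers(1, 3),
        f=st.floats(0.001, 0.4),
    )
    @settings(max_examples=60, deadline=None)
    def test_r1_equivalence_with_closed_form(self, p, q, f):
        assert n_for_r(p, q, 1, f).n == n_at_least_one(p, q, f).n

    @pytest.mark.parametrize("f", [0.01, 0.05, 0.1])
    @pytest.mark.parametrize("p", [0.25, 0.46875, 0.5, 0.75])
    def test_exceeds_mean_based_estimate_at_breeding_risks(self, p, f):
        """At the failure risks used in practice, the naive Mendelian
        estimate (which fails about half the time) is always below the
        binomial sizing."""
        for q in (1, 2, 3):
            for r in (1, 5, 20, 100):
                assert n_for_r(p, q, r, f).n >= naive_mendelian_n(p, q, r)


class TestRecombinantSelection:
    def test_worked_examples(self):
        assert n_recombinant(0.5, 0.01, q=1, r=1, f=0.05).n == 598
        assert n_recombinant(0.5, 0.01, q=1, r=2, f=0.05).n == 947
        assert n_recombinant(0.75, 0.01, q=1, r=1, f=0.05).n == 398

    def test_full_map_distance_reduces_to_plain_sizing(self):
        assert n_recombinant(0.5, 1.0, q=2, r=4, f=0.05).n == n_for_r(0.5, 2, 4, 0.05).n

    def test_per_locus_distances(self):
        res = solve(SelectionTarget(p=0.5, q=2, r=1, f=0.05, d=(0.01, 0.02)))
        assert res.effective_p == pytest.approx(0.005 * 0.01, rel=1e-12)

    def test_invalid_distance_rejected(self):
        with pytest.raises(ValueError, match="Morgans"):
            SelectionTarget(p=0.5, q=1, r=1, f=0.05, d=(0.0,))

    def test_target_from_generation(self):
        target = SelectionTarget.from_generation("BC1", "include_het", r=2, d=[0.01])
        assert solve(target).n == 947


class TestNaiveMendelian:
    @pytest.mark.parametrize(
        "p, q, r, expected",
        [(0.46875, 2, 100, 455), (0.5, 1, 1, 2), (0.25, 1, 10, 40)],
    )
    def test_rounds_mean_to_nearest(self, p, q, r, expected):
        assert naive_mendelian_n(p, q, r) == expected


class TestExpectedPositives:
    def test_bc_deployment_example(self):
        mean = expected_positives(145, 0.5, 4)
        assert mean == 9.0625
        assert round(mean) == 9

    def test_forward_breeding_example(self):
        assert expected_positives(455, 0.46875, 2) == pytest.approx(100, abs=0.05)

    def test_zero_probability(self):
        assert expected_positives(100, 0.0, 1) == 0.0


class TestTwoStagePlan:
    def test_single_locus_enrichment_is_less_efficient(self):
        plan = two_stage_plan(1, 50, 0.01)
        assert plan.total_genotyped > plan.single_stage_genotyped

    def test_multi_locus_saves_plant_generations(self):
        plan = two_stage_plan(3, 50, 0.01)
        assert plan.plant_generations < plan.single_stage_plant_generations

    def test_stage_sizes_cover_their_risks(self):
        plan = two_stage_plan(2, 20, 0.01)
        assert failure_probability(plan.n_fixed, plan.enriched_p, 2, 20) <= 0.005
        assert failure_probability(plan.n_f2, 0.75, 2, plan.n_fixed) <= 0.005

    def test_degenerate_risk_gives_minimal_sizes(self):
        plan = two_stage_plan(1, 1, 0.99)
        assert plan.n_fixed >= 1 and plan.n_f2 >= 1
        assert plan.n_f2 <= 3

    def test_risk_split_validated(self):
        with pytest.raises(ValueError):
            two_stage_plan(1, 1, 0.05, risk_split=1.0)


class TestCompareStrategies:
    def test_single_stage_column_reproduces_forward_breeding_size(self):
        table = compare_strategies(2, 100, 0.01)
        assert table.loc["single_stage_fixed", "total_genotyped"] == 555

    def test_single_stage_strictly_increasing_in_loci(self):
        sizes = [
            compare_strategies(q, 50, 0.01).loc["single_stage_fixed", "n_stage1"]
            for q in range(1, 6)
        ]
        assert all(a < b for a, b in zip(sizes, sizes[1:]))


class TestSizeTables:
    def test_shapes_and_monotonicity(self):
        t1 = forward_breeding_table()
        t2 = line_augmentation_table()
        for table in (t1, t2):
            assert table.shape == (5, 3)
            assert (table.diff().dropna() > 0).all().all()  # more loci -> bigger
            assert (table.T.diff().dropna() > 0).all().all()  # more lines -> bigger

    def test_each_added_locus_just_over_doubles_the_population(self):
        t1 = forward_breeding_table()
        ratios = (t1.shift(-1) / t1).dropna()
        assert ((ratios > 2.0) & (ratios < 2.5)).all().all()
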