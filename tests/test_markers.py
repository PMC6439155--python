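"""Marker grading: FPR/FNR, ranking, cross prediction, QTL profiles."""

import pandas as pd
import pytest

from conftest import build_panel
from masplan.markers import (
    HetPolicy,
    evaluate_marker,
    mas_success_matrix,
    qtl_profile,
    rank_markers,
)


class TestEvaluateMarker:
    def test_false_negative_on_one_of_two_donors(self, validation_panel):
        acc = evaluate_marker(validation_panel, "m1")
        assert acc.fnr == 0.5
        assert acc.fpr == 0.0
        assert acc.call_rate == 1.0
        assert (acc.n_pos_scored, acc.n_neg_scored) == (2, 5)

    def test_false_positives_on_recipients(self, validation_panel):
        acc = evaluate_marker(validation_panel, "m2")
        assert acc.fpr == pytest.approx(3 / 5)
        assert acc.fnr == 0.0

    def test_concordant_marker_is_perfect(self, validation_panel):
        acc = evaluate_marker(validation_panel, "m3")
        assert acc.fpr == 0.0 and acc.fnr == 0.0

    def test_het_policy_flips_het_calls(self):
        panel = build_panel({
            "d1": ("donor", "positive", {"m": "H"}),
            "r1": ("recipient", "negative", {"m": "B"}),
        })
        assert evaluate_marker(panel, "m", HetPolicy.HET_AS_POSITIVE).fnr == 0.0
        assert evaluate_marker(panel, "m", HetPolicy.HET_AS_NEGATIVE).fnr == 1.0

    def test_missing_calls_excluded_from_denominators(self):
        panel = build_panel({
            "d1": ("donor", "positive", {"m": "A"}),
            "d2": ("donor", "positive", {"m": None}),
            "r1": ("recipient", "negative", {"m": "A"}),
            "r2": ("recipient", "negative", {"m": None}),
            "u1": ("other", "unknown", {"m": "A"}),
        })
        acc = evaluate_marker(panel, "m")
        assert (acc.n_pos_scored, acc.n_neg_scored) == (1, 1)
        assert acc.fpr == 1.0 and acc.fnr == 0.0
        assert acc.call_rate == pytest.approx(3 / 5)  # over all lines

    def test_unknown_status_lines_do_not_enter_rates(self):
        panel = build_panel({
            "d1": ("donor", "positive", {"m": "A"}),
            "r1": ("recipient", "negative", {"m": "B"}),
            "u1": ("other", "unknown", {"m": "A"}),
            "u2": ("other", "unknown", {"m": "B"}),
        })
        acc = evaluate_marker(panel, "m")
        assert acc.fpr == 0.0 and acc.fnr == 0.0

    def test_all_missing_is_an_error_not_zero(self):
        panel = build_panel({
            "d1": ("donor", "positive", {"m": None}),
            "r1": ("recipient", "negative", {"m": None}),
        })
        with pytest.raises(ValueError, match="QTL-positive"):
            evaluate_marker(panel, "m")

    def test_row_and_duplication_invariance(self, validation_panel):
        baseline = evaluate_marker(validation_panel, "m1")
        lines = validation_panel.lines.iloc[::-1]
        calls = validation_panel.calls.iloc[::-1]
        from masplan.markers import GenotypePanel

        reordered = GenotypePanel(lines, calls)
        acc = evaluate_marker(reordered, "m1")
        assert (acc.fpr, acc.fnr) == (baseline.fpr, baseline.fnr)
        # adding a line whose call is missing leaves the rates unchanged
        lines2 = pd.concat([
            validation_panel.lines,
            pd.DataFrame({"role": ["recipient"], "qtl_status": ["negative"]},
                         index=["extra"]),
        ])
        calls2 = pd.concat([
            validation_panel.calls,
            pd.DataFrame({m: [pd.NA] for m in validation_panel.marker_ids},
                         index=["extra"], dtype="string"),
        ])
        padded = GenotypePanel(lines2.rename_axis("line_id"),
                               calls2.rename_axis("line_id"))
        acc2 = evaluate_marker(padded, "m1")
        assert (acc2.fpr, acc2.fnr) == (baseline.fpr, baseline.fnr)


class TestRankMarkers:
    def test_concordant_marker_ranks_first(self, validation_panel):
        ranked = rank_markers(validation_panel)
        assert [a.marker_id for a in ranked] == ["m3", "m1", "m2"]

    def test_false_positives_outrank_false_negatives(self, validation_panel):
        # m1 (FNR 0.5, FPR 0) must beat m2 (FPR 0.6): FPR dominates
        ranked = [a.marker_id for a in rank_markers(validation_panel)]
        assert ranked.index("m1") < ranked.index("m2")

    def test_identical_markers_tie_break_lexicographically(self):
        panel = build_panel({
            "d1": ("donor", "positive", {"b": "A", "a": "A"}),
            "r1": ("recipient", "negative", {"b": "B", "a": "B"}),
        })
        assert [a.marker_id for a in rank_markers(panel)] == ["a", "b"]


class TestMasSuccessMatrix:
    def test_marker_failing_one_donor_fails_all_its_crosses(self, validation_panel):
        pred = mas_success_matrix(validation_panel, "m1")
        assert pred.n_crosses == 10
        assert pred.n_success == 5
        assert pred.matrix.loc["donor_1"].all()
        assert not pred.matrix.loc["donor_2"].any()

    def test_concordant_marker_succeeds_everywhere(self, validation_panel):
        pred = mas_success_matrix(validation_panel, "m3")
        assert pred.n_success == pred.n_crosses == 10
        assert pred.success_fraction == 1.0

    def test_false_positive_recipient_blocks_the_cross(self):
        panel = build_panel({
            "d1": ("donor", "positive", {"m": "A"}),
            "r1": ("recipient", "negative", {"m": "A"}),
        })
        assert mas_success_matrix(panel, "m").n_success == 0

    def test_needs_both_roles(self):
        panel = build_panel({
            "d1": ("donor", "positive", {"m": "A"}),
            "d2": ("donor", "positive", {"m": "A"}),
        })
        with pytest.raises(ValueError, match="recipient"):
            mas_success_matrix(panel, "m")


class TestQtlProfile:
    def test_profile_reflects_calls(self, validation_panel):
        profile = qtl_profile(
            validation_panel, {"m1": "qA", "m2": "qB", "m3": "qC"}
        )
        # the concordant marker reproduces the true status column
        status = validation_panel.lines["qtl_status"]
        assert (profile["qC"] == status).all()

    def test_het_and_missing_reported(self):
        panel = build_panel({
            "d1": ("donor", "positive", {"m": "H"}),
            "r1": ("recipient", "negative", {"m": None}),
        })
        profile = qtl_profile(panel, {"m": "q"})
        assert profile.loc["d1", "q"] == "heterozygous"
        assert profile.loc["r1", "q"] == "missing"

    def test_unmapped_markers_warn_and_are_ignored(self, validation_panel):
        with pytest.warns(UserWarning, match="m2"):
            profile = qtl_profile(validation_panel, {"m1": "qA", "m3": "qC"})
        assert list(profile.columns) == ["qA", "qC"]

    def test_unknown_mapped_marker_is_an_error(self, validation_panel):
        with pytest.raises(KeyError, match="mX"):
            qtl_profile(validation_panel, {"mX": "qA"})
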