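"""Threshold-validation statistics: 2x2 odds ratio, Woolf CI, logistic
equivalence, and the cohort stratification tables."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.contingency_tables import Table2x2

from tardivo import (
    CohortRecord,
    ContingencyTable2x2,
    FootAssessment,
    Outcome,
    ZeroCellPolicy,
    build_contingency,
    healing_time_by_site,
    logistic_or_2x2,
    odds_ratio_woolf,
    pad_outcome_table,
    round_half_up,
    stratify_scores,
)


def _rec(pid, wagner, pad, site, outcome, days=None):
    return CohortRecord(
        pid, FootAssessment.from_values(wagner, pad, site, pid), outcome, days
    )


cells = st.integers(min_value=1, max_value=60)


class TestContingency:
    def test_fixture_reconstruction(self, study_cohort):
        """Amputation-vs-cure cross-tabulation at the score-12 threshold."""
        t = build_contingency(study_cohort)
        assert (t.a, t.b, t.c, t.d) == (8, 2, 1, 38)

    def test_single_record(self):
        t = build_contingency([_rec("x", 4, 2, "HF4", Outcome.AMPUTATION)])
        assert (t.a, t.b, t.c, t.d) == (1, 0, 0, 0)

    def test_referred_outcomes_are_excluded(self, study_cohort):
        t = build_contingency(study_cohort)
        analysable = [
            r
            for r in study_cohort
            if r.outcome in (Outcome.AMPUTATION, Outcome.CLINICAL_CURE)
        ]
        assert t.a + t.b + t.c + t.d == len(analysable) == 49

    def test_no_analysable_outcomes(self):
        only_ortho = [_rec("x", 2, 1, "FF1", Outcome.ORTHOPEDIC_TREATMENT)]
        with pytest.raises(ValueError, match="no analysable outcomes"):
            build_contingency(only_ortho)

    def test_empty_cohort(self):
        with pytest.raises(ValueError, match="empty"):
            build_contingency([])

    def test_threshold_must_be_attainable(self, study_cohort):
        with pytest.raises(ValueError, match="attainable"):
            build_contingency(study_cohort, threshold=11)

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            ContingencyTable2x2(1, -1, 0, 2)


class TestWoolfOddsRatio:
    def test_study_table(self):
        """8*38/(2*1) = 152 with Woolf CI rounding to (12.2, 1886.5)."""
        res = odds_ratio_woolf(ContingencyTable2x2(8, 2, 1, 38))
        assert res.odds_ratio == pytest.approx(152.0)
        assert round_half_up(res.ci_low) == 12.2
        assert round_half_up(res.ci_high) == 1886.5

    def test_unit_table_symmetric(self):
        res = odds_ratio_woolf(ContingencyTable2x2(1, 1, 1, 1))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.ci_low * res.ci_high == pytest.approx(1.0)  # log-symmetric

    def test_haldane_anscombe_adds_half_to_every_cell(self):
        res = odds_ratio_woolf(
            ContingencyTable2x2(9, 5, 0, 48),
            zero_cell_policy=ZeroCellPolicy.HALDANE_ANSCOMBE,
        )
        assert res.odds_ratio == pytest.approx((9.5 * 48.5) / (5.5 * 0.5))

    def test_zero_cell_without_correction(self):
        res = odds_ratio_woolf(ContingencyTable2x2(9, 5, 0, 48))
        assert math.isinf(res.odds_ratio)
        assert math.isnan(res.ci_low) and math.isnan(res.ci_high)
        res0 = odds_ratio_woolf(ContingencyTable2x2(0, 5, 3, 48))
        assert res0.odds_ratio == 0.0

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=60, deadline=None)
    def test_matches_independent_log_interval(self, a, b, c, d):
        """Cross-check against statsmodels' 2x2 log-OR interval."""
        ours = odds_ratio_woolf(ContingencyTable2x2(a, b, c, d))
        ref = Table2x2(np.array([[a, b], [c, d]]))
        assert ours.odds_ratio == pytest.approx(ref.oddsratio)
        lo, hi = ref.oddsratio_confint(0.05)
        assert ours.ci_low == pytest.approx(lo)
        assert ours.ci_high == pytest.approx(hi)

    @given(a=cells, b=cells, c=cells, d=cells, k=st.integers(2, 9))
    @settings(max_examples=40, deadline=None)
    def test_scale_consistency(self, a, b, c, d, k):
        """Scaling all cells by k preserves the OR and narrows the CI."""
        base = odds_ratio_woolf(ContingencyTable2x2(a, b, c, d))
        scaled = odds_ratio_woolf(ContingencyTable2x2(k * a, k * b, k * c, k * d))
        assert scaled.odds_ratio == pytest.approx(base.odds_ratio)
        assert scaled.ci_high / scaled.ci_low < base.ci_high / base.ci_low

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=40, deadline=None)
    def test_ci_brackets_estimate(self, a, b, c, d):
        res = odds_ratio_woolf(ContingencyTable2x2(a, b, c, d))
        assert res.ci_low <= res.odds_ratio <= res.ci_high

    def test_alpha_validated(self):
        with pytest.raises(ValueError, match="alpha"):
            odds_ratio_woolf(ContingencyTable2x2(1, 1, 1, 1), alpha=1.2)


class TestLogisticEquivalence:
    @pytest.mark.parametrize(
        "table, expected_or",
        [((8, 2, 1, 38), 152.0), ((1, 1, 1, 1), 1.0), ((10, 10, 5, 20), 4.0)],
    )
    def test_exp_beta_equals_cross_product(self, table, expected_or):
        beta, exp_beta = logistic_or_2x2(ContingencyTable2x2(*table))
        assert exp_beta == pytest.approx(expected_or, rel=1e-6)
        assert beta == pytest.approx(math.log(expected_or), abs=1e-6)

    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=25, deadline=None)
    def test_saturated_model_identity(self, a, b, c, d):
        """Iterative MLE recovers the closed-form cross-product OR."""
        _, exp_beta = logistic_or_2x2(ContingencyTable2x2(a, b, c, d))
        assert exp_beta == pytest.approx(a * d / (b * c), rel=1e-6)

    def test_zero_cell_has_no_finite_mle(self):
        with pytest.raises(ValueError, match="non-finite MLE"):
            logistic_or_2x2(ContingencyTable2x2(9, 5, 0, 48))


class TestStrata:
    def test_fixture_rows(self, study_cohort):
        df = stratify_scores(study_cohort).set_index("scores")
        top = df.loc["16 to 32"]
        assert (top.n, top.pct, top.cure_n, top.amputation_n, top.amputation_pct) == (
            10,
            16.1,
            0,
            7,
            70.0,
        )
        six = df.loc["6"]
        assert (six.n, six.cure_n, six.cure_pct) == (23, 19, 82.6)
        assert df.loc["1 to 4"].amputation_n == 0

    def test_counts_conserved(self, study_cohort):
        df = stratify_scores(study_cohort)
        assert df["n"].sum() == len(study_cohort)
        assert df["cure_n"].sum() == 40
        assert df["amputation_n"].sum() == 9

    def test_uncovered_score_is_an_error(self, study_cohort):
        with pytest.raises(ValueError, match="32"):
            stratify_scores(study_cohort, bins=[(1, 12)])

    def test_overlapping_bins_rejected(self, study_cohort):
        with pytest.raises(ValueError, match="overlapping"):
            stratify_scores(study_cohort, bins=[(1, 12), (12, 32)])

    def test_empty_cohort(self):
        with pytest.raises(ValueError, match="empty"):
            stratify_scores([])


class TestPadTable:
    def test_fixture_rows(self, study_cohort):
        df = pad_outcome_table(study_cohort).set_index("group")
        pad2 = df.loc["PAD 2"]
        assert (pad2.amputated_n, pad2.amputated_pct) == (9, 64.3)
        assert (pad2.not_amputated_n, pad2.not_amputated_pct) == (5, 35.7)
        pad1 = df.loc["PAD 1"]
        assert (pad1.amputated_n, pad1.not_amputated_n, pad1.not_amputated_pct) == (
            0,
            48,
            100.0,
        )
        total = df.loc["Total"]
        assert (total.amputated_pct, total.not_amputated_pct) == (14.5, 85.5)

    def test_single_record(self):
        df = pad_outcome_table([_rec("x", 2, 1, "FF1", Outcome.CLINICAL_CURE)])
        row = df.set_index("group").loc["PAD 1"]
        assert (row.amputated_n, row.not_amputated_n, row.not_amputated_pct) == (
            0,
            1,
            100.0,
        )


class TestHealingTime:
    def test_mean_per_site(self):
        cohort = [
            _rec("a", 1, 1, "HF4", Outcome.CLINICAL_CURE, 200),
            _rec("b", 1, 1, "HF4", Outcome.CLINICAL_CURE, 268),
            _rec("c", 1, 1, "FF1", Outcome.CLINICAL_CURE, 80),
        ]
        means = healing_time_by_site(cohort)
        assert means["HF4"] == pytest.approx(234.0)
        assert means["FF1"] == pytest.approx(80.0)

    def test_fixture_means_match_study(self, study_cohort):
        means = healing_time_by_site(study_cohort)
        assert means.to_dict() == pytest.approx(
            {"FF1": 80.0, "FF2": 118.0, "MF3": 123.0, "HF4": 234.0}
        )

    def test_sites_without_durations_warn_and_are_omitted(self):
        cohort = [_rec("a", 1, 1, "FF1", Outcome.AMPUTATION)]
        with pytest.warns(UserWarning, match="FF1"):
            means = healing_time_by_site(cohort)
        assert means.empty


class TestRounding:
    @pytest.mark.parametrize(
        "num, denom, expected",
        [(9, 14, 64.3), (53, 62, 85.5), (19, 23, 82.6), (28, 62, 45.2), (5, 14, 35.7)],
    )
    def test_printed_percent_convention(self, num, denom, expected):
        """Half-away-from-zero at one decimal, as in the printed tables."""
        assert round_half_up(100 * num / denom) == expected
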