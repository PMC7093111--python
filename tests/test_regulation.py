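import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regenddr import (
    QpcrStandardCurve,
    RegulationRuleConfig,
    TimecourseExpressionSet,
    VolcanoConfig,
    classify_expression_set,
    classify_microarray_gene,
    classify_rnaseq_gene,
    composite_relative_score,
    qpcr_quantify,
    summarize_categories,
    volcano_select,
)
from regenddr.errors import (
    ConfigurationError,
    DegenerateDispersionError,
    EmptyInputError,
    MalformedInputError,
)

from .oracles import regulation_scan


def _profile(d: dict[int, float]) -> pd.Series:
    return pd.Series(d)


class TestRnaseqRule:
    @pytest.mark.parametrize(
        "profile, expected, up_tps, down_tps",
        [
            ({0: 10, 3: 25, 5: 30}, "up", (3, 5), ()),
            ({0: 10, 3: 10, 5: 10, 7: 10}, "none", (), ()),
            ({0: 8, 5: 20, 14: 3}, "mixed", (5,), (14,)),
            ({0: 10, 3: 20}, "up", (3,), ()),  # inclusive: exactly 2x is up
            ({0: 10, 3: 5}, "down", (), (3,)),  # inclusive: exactly half is down
            ({0: 10, 3: 19.9, 5: 5.1}, "none", (), ()),
        ],
    )
    def test_fold_rule_examples(self, profile, expected, up_tps, down_tps):
        call = classify_rnaseq_gene("g", _profile(profile))
        assert call.category == expected
        assert call.up_timepoints == up_tps
        assert call.down_timepoints == down_tps

    def test_intact_zero_excluded_by_default(self):
        call = classify_rnaseq_gene("g", _profile({0: 0.0, 3: 5.0}))
        assert call.excluded

    def test_intact_zero_call_up_policy(self):
        rules = RegulationRuleConfig(intact_zero_policy="call_up_if_any_positive")
        call = classify_rnaseq_gene("g", _profile({0: 0.0, 3: 5.0, 7: 0.0}), rules)
        assert call.category == "up" and call.up_timepoints == (3,)

    @given(
        values=st.lists(st.floats(0.01, 1e4), min_size=3, max_size=8),
        fold=st.floats(1.1, 5.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_literal_scan(self, values, fold):
        """The classifier matches an independent per-timepoint scan."""
        profile = {0: values[0]} | {t + 1: v for t, v in enumerate(values[1:])}
        rules = RegulationRuleConfig(fold_threshold=fold)
        call = classify_rnaseq_gene("g", _profile(profile), rules)
        assert call.category == regulation_scan(profile, values[0], fold)

    @given(
        values=st.lists(st.floats(0.01, 1e4), min_size=3, max_size=8),
        scale=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, values, scale):
        """Fold-change calls depend only on ratios, not absolute level."""
        profile = {0: values[0]} | {t + 1: v for t, v in enumerate(values[1:])}
        scaled = {t: v * scale for t, v in profile.items()}
        a = classify_rnaseq_gene("g", _profile(profile))
        b = classify_rnaseq_gene("g", _profile(scaled))
        assert a.category == b.category

    def test_matrix_path_matches_per_gene_path(self, rng):
        values = pd.DataFrame(
            rng.lognormal(3, 1, size=(50, 5)),
            index=[f"g{i}" for i in range(50)],
            columns=[0, 3, 7, 14, 28],
        )
        expr = TimecourseExpressionSet(values)
        matrix_calls = classify_expression_set(expr)
        for call in matrix_calls:
            single = classify_rnaseq_gene(call.gene_id, expr.profile(call.gene_id))
            assert call == single


class TestMicroarrayRule:
    @pytest.mark.parametrize(
        "profile, expected",
        [
            ({0: 5, 7: 6.5}, "up"),
            ({0: 5, 3: 4.2, 7: 5.8}, "none"),  # strictly inside mean +/- sd
            ({0: 5, 7: 6.5, 21: 3.5}, "mixed"),
            ({0: 5, 7: 6.0}, "none"),  # exactly one sd is not "more than"
        ],
    )
    def test_sd_rule_examples(self, profile, expected):
        call = classify_microarray_gene("g", _profile(profile), 5.0, 1.0)
        assert call.category == expected

    def test_degenerate_sd_rejected(self):
        with pytest.raises(DegenerateDispersionError):
            classify_microarray_gene("g", _profile({0: 5, 7: 6}), 5.0, 0.0)

    def test_expression_set_uses_intact_replicates(self):
        values = pd.DataFrame({0: [5.0], 7: [8.0]}, index=["g"])
        reps = pd.DataFrame({"dpa0_rep1": [4.0], "dpa0_rep2": [6.0]}, index=["g"])
        expr = TimecourseExpressionSet(values, platform="microarray",
                                       intact_replicates=reps)
        (call,) = classify_expression_set(expr)
        # mean 5, sd sqrt(2): 8 > 5 + 1.414 -> up
        assert call.category == "up"


class TestSummaries:
    def test_each_category_once(self):
        calls = [
            classify_rnaseq_gene("a", _profile({0: 10, 3: 25})),
            classify_rnaseq_gene("b", _profile({0: 10, 3: 4})),
            classify_rnaseq_gene("c", _profile({0: 10, 3: 25, 7: 4})),
            classify_rnaseq_gene("d", _profile({0: 10, 3: 11})),
        ]
        summary = summarize_categories(calls)
        assert all(v == (1, 0.25) for v in summary.values())

    def test_eleven_of_seventeen_up_rounds_to_65_percent(self):
        """11 of 17 validated genes called up reports as 65%."""
        calls = []
        for i in range(11):
            calls.append(classify_rnaseq_gene(f"u{i}", _profile({0: 1, 3: 5})))
        for i in range(6):
            calls.append(classify_rnaseq_gene(f"n{i}", _profile({0: 1, 3: 1})))
        summary = summarize_categories(calls)
        count, frac = summary["up"]
        assert count == 11
        assert frac == pytest.approx(11 / 17)
        assert round(100 * frac) == 65

    def test_fractions_sum_to_one(self, rng):
        calls = [
            classify_rnaseq_gene(f"g{i}", _profile({0: 1.0, 3: rng.lognormal()}))
            for i in range(40)
        ]
        summary = summarize_categories(calls)
        assert sum(f for _, f in summary.values()) == pytest.approx(1.0, abs=1e-12)
        assert sum(c for c, _ in summary.values()) == 40

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            summarize_categories([])


class TestCompositeScore:
    def test_intact_score_is_exactly_one(self, small_expr):
        score = composite_relative_score(small_expr, small_expr.gene_ids)
        assert score[0] == 1.0

    def test_mean_of_relative_values(self):
        values = pd.DataFrame({0: [1.0, 2.0], 14: [2.0, 8.0]}, index=["a", "b"])
        expr = TimecourseExpressionSet(values)
        score = composite_relative_score(expr, ["a", "b"])
        assert score[14] == pytest.approx(3.0)  # mean of ratios 2 and 4

    def test_intact_zero_gene_excluded(self):
        values = pd.DataFrame(
            {0: [1.0, 2.0, 0.0], 14: [2.0, 8.0, 7.0]}, index=["a", "b", "z"]
        )
        expr = TimecourseExpressionSet(values)
        score = composite_relative_score(expr, ["a", "b", "z"])
        assert score[14] == pytest.approx(3.0)

    def test_all_excluded_raises(self):
        values = pd.DataFrame({0: [0.0], 14: [7.0]}, index=["z"])
        with pytest.raises(EmptyInputError):
            composite_relative_score(TimecourseExpressionSet(values), ["z"])


class TestVolcanoSelect:
    @pytest.fixture
    def table(self):
        return pd.DataFrame(
            {
                "q_value": [0.01, 0.1, 0.01, 0.01, 0.04],
                "fold_change": [3.0, 5.0, 2.0, 0.3, 0.5],
            },
            index=["sig_up", "nonsig", "boundary_fc", "sig_down", "boundary_dn"],
        )

    def test_strict_cutoffs(self, table):
        up, down = volcano_select(table)
        assert up == {"sig_up"}
        assert down == {"sig_down"}  # FC 0.5 is exactly 1/2: excluded

    def test_sets_disjoint(self, rng):
        table = pd.DataFrame(
            {
                "q_value": rng.uniform(0, 0.2, 200),
                "fold_change": rng.lognormal(0, 1.5, 200),
            },
            index=[f"g{i}" for i in range(200)],
        )
        up, down = volcano_select(table)
        assert not up & down

    def test_nonpositive_fc_rejected(self):
        table = pd.DataFrame({"q_value": [0.01], "fold_change": [0.0]}, index=["g"])
        with pytest.raises(MalformedInputError):
            volcano_select(table)


class TestQpcr:
    CURVE = QpcrStandardCurve(slope=-3.321928, intercept=20.0)

    @pytest.mark.parametrize(
        "ct, minus_rt, reference, expected",
        [
            (20.0, 0.0, 1.0, 1.0),
            (16.678072, 0.0, 1.0, 10.0),  # one log10 unit above the intercept
        ],
    )
    def test_standard_curve(self, ct, minus_rt, reference, expected):
        assert qpcr_quantify(ct, self.CURVE, reference, minus_rt) == pytest.approx(
            expected, rel=1e-6
        )

    def test_minus_rt_subtraction_and_normalization(self):
        # raw quantity 5, genomic contamination 2, reference 3 -> 1.0
        ct = 20.0 + self.CURVE.slope * math.log10(5.0)
        assert qpcr_quantify(ct, self.CURVE, 3.0, 2.0) == pytest.approx(1.0, rel=1e-9)

    def test_subtraction_floors_at_zero(self):
        assert qpcr_quantify(20.0, self.CURVE, 1.0, 5.0) == 0.0

    def test_positive_slope_rejected(self):
        with pytest.raises(ConfigurationError):
            QpcrStandardCurve(slope=3.3, intercept=20.0)
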