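"""Selection rules: percentile cutoffs, lowest-k per classroom, skewness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from screenbias import (
    EligibilityCriterion,
    apply_criteria,
    default_criteria,
    sample_skewness,
    select_by_percentile,
    select_lowest_k_per_classroom,
)


def table_from_pretests(pretests, classrooms=None):
    n = len(pretests)
    return pd.DataFrame(
        {
            "student_id": np.arange(n),
            "classroom_id": classrooms if classrooms is not None else np.ones(n, int),
            "pretest": np.asarray(pretests, dtype=float),
        }
    )


class TestCriterionValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(method="percentile_at_or_below"),  # missing p
            dict(method="percentile_at_or_below", percentile=40, k=4),  # both
            dict(method="percentile_at_or_below", percentile=0),
            dict(method="percentile_at_or_below", percentile=100),
            dict(method="percentile_at_or_below", percentile=40, basis="census"),
            dict(method="lowest_k_per_classroom"),  # missing k
            dict(method="lowest_k_per_classroom", k=0),
            dict(method="no_such_method", percentile=40),
        ],
    )
    def test_invalid_parameterizations(self, kw):
        with pytest.raises(ValueError):
            EligibilityCriterion("bad", **kw)


class TestPercentileSelection:
    def test_interpolated_quantile_oracle(self):
        # 40th sample quantile of 1..10 by linear interpolation is 4.6,
        # so exactly {1,2,3,4} fall at or below it
        table = table_from_pretests(range(1, 11))
        flags = select_by_percentile(table, 40)
        assert list(table.loc[flags, "pretest"]) == [1, 2, 3, 4]
        assert np.quantile(table["pretest"], 0.4) == pytest.approx(4.6)

    def test_full_inclusion_at_p100(self):
        table = table_from_pretests(np.random.default_rng(0).normal(size=50))
        assert select_by_percentile(table, 100).all()

    def test_default_counts_on_simulated_population(self, default_population):
        assert select_by_percentile(default_population, 40).sum() == 2000
        assert select_by_percentile(default_population, 25).sum() == 1250

    def test_continuous_count_rule(self):
        # with continuous data the interpolated quantile sits between order
        # statistics floor(h) and floor(h)+1 where h = (n-1)p/100 + 1, so
        # exactly floor(h) students are at or below it (= floor(p*n/100)
        # at the study's n=5000 with p=40 or 25)
        rng = np.random.default_rng(3)
        table = table_from_pretests(rng.normal(size=997))
        for p in (25, 40, 63.5):
            expected = int(np.floor(996 * p / 100 + 1))
            assert select_by_percentile(table, p).sum() == expected

    def test_population_basis_uses_normal_quantile(self):
        table = table_from_pretests([-3.0, -0.3, -0.2, 0.0, 2.0])
        flags = select_by_percentile(table, 40, basis="population")
        # standard-normal 40th percentile is about -0.253
        assert list(table.loc[flags, "pretest"]) == [-3.0, -0.3]

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_by_percentile(table_from_pretests([]), 40)

    @settings(derandomize=True, max_examples=30)
    @given(
        p=st.tuples(
            st.floats(min_value=1, max_value=99),
            st.floats(min_value=1, max_value=99),
        ).filter(lambda t: t[0] < t[1]),
        seed=st.integers(0, 2**16),
    )
    def test_monotone_nesting(self, p, seed):
        """Lower percentile cutoffs select subsets of higher ones."""
        table = table_from_pretests(np.random.default_rng(seed).normal(size=80))
        lo = select_by_percentile(table, p[0])
        hi = select_by_percentile(table, p[1])
        assert (~lo | hi).all()


class TestLowestKPerClassroom:
    def test_order_statistics_by_inspection(self):
        table = table_from_pretests([0.5, -1.2, 0.3, -0.4, 2.0])
        flags = select_lowest_k_per_classroom(table, 2)
        assert sorted(table.loc[flags, "pretest"]) == [-1.2, -0.4]

    def test_k_equals_class_size_selects_all(self):
        table = table_from_pretests([0.5, -1.2, 0.3])
        assert select_lowest_k_per_classroom(table, 3).all()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_count_invariance(self, default_config, seed):
        from screenbias import simulate_population

        table = simulate_population(default_config, seed)
        assert select_lowest_k_per_classroom(table, 4).sum() == 4 * 250

    def test_undersized_classroom_rejected(self):
        table = table_from_pretests([1.0, 2.0, 3.0], classrooms=[1, 1, 2])
        with pytest.raises(ValueError, match="fewer than k"):
            select_lowest_k_per_classroom(table, 2)

    def test_ties_break_by_student_id(self):
        table = table_from_pretests([0.0, 0.0, 0.0, 1.0])
        flags = select_lowest_k_per_classroom(table, 2)
        assert list(table.loc[flags, "student_id"]) == [0, 1]


class TestApplyCriteria:
    def test_default_flag_totals(self, default_population):
        counts = {
            c.flag_column: int(default_population[c.flag_column].sum())
            for c in default_criteria()
        }
        assert counts == {
            "eligible_method_1": 2000,
            "eligible_method_2": 1250,
            "eligible_method_3": 1000,
        }

    def test_stricter_percentile_is_nested(self, default_population):
        m1 = default_population["eligible_method_1"]
        m2 = default_population["eligible_method_2"]
        assert (~m2 | m1).all()

    def test_empty_criterion_list_is_identity(self, default_population):
        base = default_population.drop(
            columns=[c for c in default_population if c.startswith("eligible_")]
        )
        pd.testing.assert_frame_equal(apply_criteria(base, []), base)

    def test_duplicate_names_rejected(self):
        crits = [
            EligibilityCriterion("m", "percentile_at_or_below", percentile=40),
            EligibilityCriterion("m", "percentile_at_or_below", percentile=25),
        ]
        with pytest.raises(ValueError, match="duplicate"):
            apply_criteria(table_from_pretests([1.0, 2.0]), crits)

    def test_selection_ignores_posttest_and_condition(self, default_population):
        """Permuting posttest (and condition) changes no eligibility flag."""
        rng = np.random.default_rng(7)
        shuffled = default_population.copy()
        shuffled["posttest"] = rng.permutation(shuffled["posttest"].to_numpy())
        shuffled["condition"] = rng.permutation(shuffled["condition"].to_numpy())
        base = shuffled.drop(
            columns=[c for c in shuffled if c.startswith("eligible_")]
        )
        reflagged = apply_criteria(base, default_criteria())
        for crit in default_criteria():
            np.testing.assert_array_equal(
                reflagged[crit.flag_column], default_population[crit.flag_column]
            )

    def test_condition_balance_among_eligible(self, default_population):
        """Selection ignores condition, so eligible groups stay ~half treated."""
        for crit in default_criteria():
            sub = default_population[default_population[crit.flag_column]]
            frac = (sub["condition"] == "treatment").mean()
            # 3-sigma binomial band around 0.5 at the subsample size
            assert abs(frac - 0.5) < 3 * 0.5 / np.sqrt(len(sub))


class TestSampleSkewness:
    def test_symmetric_sample_is_zero(self):
        assert sample_skewness([1, 2, 3]) == pytest.approx(0.0)
        assert sample_skewness([-2, -1, 0, 1, 2]) == pytest.approx(0.0)

    def test_hand_computed_moments(self):
        # (0,0,0,1): m2 = 0.1875, m3 = 0.09375, g1 = m3/m2^1.5 = 2/sqrt(3)
        def g1(x):
            x = np.asarray(x, float)
            d = x - x.mean()
            return (d**3).mean() / (d**2).mean() ** 1.5

        vals = [0, 0, 0, 1]
        assert sample_skewness(vals) == pytest.approx(2 / np.sqrt(3))
        assert sample_skewness(vals) == pytest.approx(g1(vals))

    def test_adjusted_variant(self):
        vals = [0, 0, 0, 1]
        n = 4
        factor = np.sqrt(n * (n - 1)) / (n - 2)
        assert sample_skewness(vals, adjusted=True) == pytest.approx(
            factor * sample_skewness(vals)
        )

    @pytest.mark.parametrize("vals", [[1, 2], [3, 3, 3, 3]])
    def test_degenerate_inputs_rejected(self, vals):
        with pytest.raises(ValueError):
            sample_skewness(vals)

    def test_selected_sample_is_negatively_skewed(self, default_population):
        """Truncating the upper tail leaves a left-skewed eligible sample."""
        sub = default_population[default_population["eligible_method_1"]]
        assert sample_skewness(sub["pretest"]) < -0.7
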