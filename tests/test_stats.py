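"""Statistics layer: Wilcoxon, ICC(2,1), repeated-measures ANOVA, Tukey."""

import numpy as np
import pandas as pd
import pytest

from ccfd.stats import (
    MetricMatrix,
    build_comparison_tables,
    icc2,
    mixed_factorial_anova,
    repeated_measures_comparison,
    tukey_posthoc,
    wilcoxon_signed_rank,
)
from ccfd.synthetic import simulate_metric_cohort
from oracles import (
    icc2_oracle,
    rm_anova_oracle,
    studentized_range_sf_oracle,
    wilcoxon_exact_enum,
)


class TestWilcoxon:
    def test_identical_pairs_degenerate(self):
        a = np.arange(8.0)
        res = wilcoxon_signed_rank(a, a)
        assert res.p_value == 1.0 and res.method == "degenerate"

    def test_all_positive_n6_exact(self):
        res = wilcoxon_signed_rank(np.arange(1.0, 7) + 5, np.arange(1.0, 7))
        assert res.p_value == pytest.approx(2 / 64)
        assert res.method == "exact"

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(6, 13)
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        res = wilcoxon_signed_rank(a, b)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(wilcoxon_exact_enum(a, b), abs=1e-12)

    def test_exact_handles_tied_differences(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        b = a - np.array([1.0, 1.0, -1.0, 2.0, 2.0, -2.0, 3.0])
        res = wilcoxon_signed_rank(a, b)
        assert res.p_value == pytest.approx(wilcoxon_exact_enum(a, b), abs=1e-12)

    def test_symmetry_under_sample_swap(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=10), rng.normal(size=10)
        assert wilcoxon_signed_rank(a, b).p_value == pytest.approx(
            wilcoxon_signed_rank(b, a).p_value
        )
        a, b = rng.normal(size=30), rng.normal(size=30)
        assert wilcoxon_signed_rank(a, b).p_value == pytest.approx(
            wilcoxon_signed_rank(b, a).p_value
        )

    def test_too_few_nonzero_differences_refused(self):
        with pytest.raises(ValueError, match=">= 5"):
            wilcoxon_signed_rank(np.array([1.0, 2, 3, 3]), np.array([0.0, 1, 2, 3]))


class TestICC:
    def test_identical_columns_perfect_agreement(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=8)
        m = MetricMatrix(np.tile(col[:, None], (1, 3)), tuple(range(8)),
                         ("a", "b", "c"))
        res = icc2(m)
        assert res.icc == pytest.approx(1.0)

    def test_pure_noise_without_subject_variance_near_zero(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(100, 3))
        res = icc2(MetricMatrix(v, tuple(range(100)), ("a", "b", "c")))
        assert abs(res.icc) < 0.1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_mean_squares_oracle(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=(5, 3)) + rng.normal(size=(5, 1))
        res = icc2(MetricMatrix(v, tuple(range(5)), ("a", "b", "c")))
        assert res.icc == pytest.approx(icc2_oracle(v), abs=1e-10)
        assert res.ci_low <= res.icc <= res.ci_high

    def test_matches_pingouin_reference(self):
        import pingouin as pg

        rng = np.random.default_rng(7)
        v = rng.normal(size=(12, 4)) + 2 * rng.normal(size=(12, 1))
        res = icc2(MetricMatrix(v, tuple(range(12)), tuple("abcd")))
        df = pd.DataFrame({
            "t": np.repeat(np.arange(12), 4),
            "r": list("abcd") * 12,
            "v": v.ravel(),
        })
        row = pg.intraclass_corr(df, "t", "r", "v").set_index("Type").loc["ICC(A,1)"]
        assert res.icc == pytest.approx(row.ICC, abs=1e-10)
        assert res.ci_low == pytest.approx(row.CI95[0], abs=5e-3)
        assert res.ci_high == pytest.approx(row.CI95[1], abs=5e-3)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=(10, 3)) + rng.normal(size=(10, 1))
        base = icc2(MetricMatrix(v, tuple(range(10)), ("a", "b", "c"))).icc
        shifted = icc2(
            MetricMatrix(v + 100.0, tuple(range(10)), ("a", "b", "c"))
        ).icc
        scaled = icc2(
            MetricMatrix(v * 3.5, tuple(range(10)), ("a", "b", "c"))
        ).icc
        assert shifted == pytest.approx(base, abs=1e-10)
        assert scaled == pytest.approx(base, abs=1e-10)

    def test_zero_variance_refused(self):
        m = MetricMatrix(np.full((5, 3), 2.0), tuple(range(5)), ("a", "b", "c"))
        with pytest.raises(ValueError, match="variance"):
            icc2(m)


class TestRepeatedMeasures:
    def test_null_configuration_subject_offsets_only(self):
        offsets = np.array([1.0, 5.0, -2.0, 7.0])[:, None]
        m = MetricMatrix(np.tile(offsets, (1, 3)), tuple(range(4)),
                         ("a", "b", "c"))
        res = repeated_measures_comparison(m)
        assert res.p_condition == 1.0

    def test_matches_hand_anova_and_statsmodels(self):
        rng = np.random.default_rng(4)
        v = rng.normal(size=(4, 3)) + np.array([0.0, 1.0, 0.5]) \
            + rng.normal(size=(4, 1))
        m = MetricMatrix(v, tuple(range(4)), ("a", "b", "c"))
        res = repeated_measures_comparison(m)
        assert res.f_condition == pytest.approx(rm_anova_oracle(v), rel=1e-10)
        from statsmodels.stats.anova import AnovaRM

        df = pd.DataFrame({
            "s": np.repeat(np.arange(4), 3),
            "c": ["a", "b", "c"] * 4,
            "v": v.ravel(),
        })
        tab = AnovaRM(df, "v", "s", within=["c"]).fit().anova_table
        assert res.f_condition == pytest.approx(tab.loc["c", "F Value"], rel=1e-9)
        assert res.p_condition == pytest.approx(tab.loc["c", "Pr > F"], rel=1e-9)

    def test_shifted_condition_detected_in_power_simulation(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            v = rng.normal(0, 3.5, size=(23, 5)) + rng.normal(0, 7, size=(23, 1))
            v[:, 2] += 10.0
            m = MetricMatrix(v, tuple(range(23)), tuple("abcde"))
            if repeated_measures_comparison(m).p_condition < 0.05:
                hits += 1
        assert hits >= 95

    def test_two_way_within_subject_anova_runs(self):
        df = simulate_metric_cohort(n_eyes=8, seed=0)
        tab = mixed_factorial_anova(df)
        assert {"device", "slab", "device:slab"} == set(tab.index)
        assert (tab["Pr > F"] <= 1).all()


class TestTukey:
    def test_null_zero_noise_flags_nothing(self):
        offsets = np.array([1.0, 5.0, -2.0, 7.0])[:, None]
        m = MetricMatrix(np.tile(offsets, (1, 3)), tuple(range(4)),
                         ("a", "b", "c"))
        assert all(r.p_value == 1.0 for r in tukey_posthoc(m))

    def test_shifted_group_flagged_exactly(self):
        rng = np.random.default_rng(5)
        v = rng.normal(0, 0.5, size=(12, 3)) + rng.normal(0, 1, size=(12, 1))
        v[:, 1] += 10.0
        m = MetricMatrix(v, tuple(range(12)), ("a", "b", "c"))
        flagged = {
            frozenset((r.condition_a, r.condition_b))
            for r in tukey_posthoc(m) if r.p_value < 0.05
        }
        assert flagged == {frozenset(("a", "b")), frozenset(("b", "c"))}

    def test_studentized_range_tail_matches_integration(self):
        from scipy.stats import studentized_range

        for q, k, df in [(3.2, 3, 20), (4.0, 5, 44)]:
            assert studentized_range.sf(q, k, df) == pytest.approx(
                studentized_range_sf_oracle(q, k, df), abs=1e-4
            )

    def test_two_conditions_refused(self):
        m = MetricMatrix(np.random.default_rng(0).normal(size=(6, 2)),
                         tuple(range(6)), ("a", "b"))
        with pytest.raises(ValueError, match="3 conditions"):
            tukey_posthoc(m)


class TestComparisonTables:
    def test_planted_device_offset_flagged_in_all_slabs(self):
        df = simulate_metric_cohort(n_eyes=23, seed=1)
        tables = build_comparison_tables(df, metrics=("fd_percent",))
        col = "p SD_V1 vs SS"
        assert (tables.table1[col] < 0.05).all()

    def test_mean_sd_formatting_two_decimals(self):
        df = simulate_metric_cohort(n_eyes=10, seed=2)
        tables = build_comparison_tables(df, metrics=("fd_percent",))
        cell = tables.table1.iloc[0]["SS"]
        import re

        assert re.fullmatch(r"-?\d+\.\d{2} ± \d+\.\d{2}", cell)

    def test_incomplete_design_refused_with_cells(self):
        df = simulate_metric_cohort(n_eyes=6, seed=3)
        df = df.drop(df.index[0])
        with pytest.raises(ValueError, match="missing cells"):
            build_comparison_tables(df, metrics=("fd_percent",))

    def test_matrix_from_long_rejects_missing(self):
        df = simulate_metric_cohort(n_eyes=4, seed=4)
        df = df[~((df.eye_id == "eye00") & (df.slab == "11-21")
                  & (df.device == "SS"))]
        with pytest.raises(ValueError, match="missing"):
            MetricMatrix.from_long(df[df.device == "SS"], "fd_percent", "slab")
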