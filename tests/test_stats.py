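import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synquant.stats import (
    GroupDataset,
    conditional_log_transform,
    dagostino_pearson,
    geometric_mean_ci,
    one_way_anova,
    sidak_adjust,
    sidak_pairwise,
    spearman_heteroscedasticity,
    two_way_anova,
)

GENOS = np.array(["WT", "DS"])
AGES = np.array(["2W", "4W", "8W"])


def factorial_dataset(values_2x3xn):
    v = np.asarray(values_2x3xn, dtype=float)
    n = v.shape[2]
    return GroupDataset(
        v.ravel(),
        np.repeat(GENOS, 3 * n),
        np.tile(np.repeat(AGES, n), 2),
    )


def balanced_anova_oracle(v):
    """Closed-form balanced two-way ANOVA F statistics."""
    a, b, n = v.shape
    gm = v.mean()
    ssA = b * n * ((v.mean(axis=(1, 2)) - gm) ** 2).sum()
    ssB = a * n * ((v.mean(axis=(0, 2)) - gm) ** 2).sum()
    cell = v.mean(axis=2)
    ssAB = n * ((cell - v.mean(axis=(1, 2))[:, None] - v.mean(axis=(0, 2))[None, :] + gm) ** 2).sum()
    msE = ((v - cell[:, :, None]) ** 2).sum() / (a * b * (n - 1))
    return ssA / (a - 1) / msE, ssB / (b - 1) / msE, ssAB / ((a - 1) * (b - 1)) / msE


class TestNormalityAndVariance:
    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="n >= 8"):
            dagostino_pearson([1, 2, 3, 4, 5])

    def test_size_on_normal_samples(self):
        rej = sum(dagostino_pearson(np.random.default_rng(s).normal(0, 1, 5000))[1] < 0.05
                  for s in range(200))
        assert 0.02 <= rej / 200 <= 0.09

    def test_power_on_lognormal_samples(self):
        rej = sum(dagostino_pearson(np.exp(np.random.default_rng(s).normal(0, 1, 100)))[1] < 0.05
                  for s in range(20))
        assert rej >= 18

    def test_spearman_perfect_monotone(self):
        fitted = np.arange(1.0, 21.0)
        rho, _ = spearman_heteroscedasticity(fitted * 0.1, fitted)
        assert rho == pytest.approx(1.0)

    def test_spearman_power_on_proportional_variance(self):
        hits = 0
        for s in range(20):
            r = np.random.default_rng(s)
            fitted = r.uniform(1, 10, 60)
            resid = r.normal(0, fitted * 0.5)
            hits += spearman_heteroscedasticity(resid, fitted)[1] < 0.05
        assert hits >= 18

    def test_spearman_size_on_homoscedastic_data(self):
        hits = 0
        for s in range(40):
            r = np.random.default_rng(500 + s)
            fitted = r.uniform(1, 10, 60)
            hits += spearman_heteroscedasticity(r.normal(0, 1, 60), fitted)[1] < 0.05
        assert hits <= 6  # near-nominal rejection

    def test_constant_fitted_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_heteroscedasticity(np.arange(6.0), np.ones(6))


class TestConditionalLogTransform:
    def test_plus_one_rule_fires_when_any_point_at_or_below_1hz(self):
        ds = GroupDataset(np.array([0.5, 2.0]), np.array(["WT", "DS"]), np.array(["2W", "2W"]))
        out = conditional_log_transform(ds)
        np.testing.assert_allclose(out.values, np.log10([1.5, 3.0]))
        assert out.transform_applied == "log10_plus1"

    def test_no_constant_added_when_all_above_1hz(self):
        ds = GroupDataset(np.array([2.0, 4.0]), np.array(["WT", "DS"]), np.array(["2W", "2W"]))
        out = conditional_log_transform(ds)
        np.testing.assert_allclose(out.values, np.log10([2.0, 4.0]))
        assert out.transform_applied == "log10"

    def test_nonpositive_value_rejected(self):
        ds = GroupDataset(np.array([0.0, 2.0]), np.array(["WT", "DS"]), np.array(["2W", "2W"]))
        with pytest.raises(ValueError, match="positive"):
            conditional_log_transform(ds)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(1e-6, 1e3), min_size=2, max_size=20))
    def test_transformed_values_always_positive(self, vals):
        ds = GroupDataset(np.array(vals), np.array(["WT"] * len(vals)), np.array(["2W"] * len(vals)))
        out = conditional_log_transform(ds)
        assert np.all(out.values > 0)


class TestAnova:
    def test_balanced_design_matches_closed_form(self, rng):
        v = rng.normal(10, 2, (2, 3, 4)) + np.arange(3)[None, :, None]
        res = two_way_anova(factorial_dataset(v))
        fA, fB, fAB = balanced_anova_oracle(v)
        assert res.effects["genotype"]["F"] == pytest.approx(fA, abs=1e-8)
        assert res.effects["age"]["F"] == pytest.approx(fB, abs=1e-8)
        assert res.effects["interaction"]["F"] == pytest.approx(fAB, abs=1e-8)
        assert res.effects["genotype"]["df_num"] == 1
        assert res.effects["age"]["df_num"] == 2
        assert res.effects["genotype"]["df_den"] == 2 * 3 * 3

    def test_empty_cell_rejected_with_identity(self):
        ds = GroupDataset(np.arange(10.0), np.repeat(GENOS, 5), np.array(["2W"] * 5 + ["4W"] * 5))
        with pytest.raises(ValueError, match="DS.*2W|2W.*DS"):
            two_way_anova(ds)

    def test_identical_values_flagged_degenerate(self):
        v = np.full((2, 3, 3), 5.0)
        res = two_way_anova(factorial_dataset(v))
        assert res.degenerate
        assert np.isnan(res.effects["genotype"]["F"])

    def test_type_i_error_near_nominal(self):
        rej = 0
        reps = 300
        for i in range(reps):
            r = np.random.default_rng(10_000 + i)
            res = two_way_anova(factorial_dataset(r.normal(0, 1, (2, 3, 6))))
            rej += res.effects["genotype"]["p"] < 0.05
        assert 0.025 <= rej / reps <= 0.08

    def test_power_increases_with_effect_size(self):
        powers = []
        for effect in (0.0, 1.0, 2.0):
            rej = 0
            for i in range(100):
                r = np.random.default_rng(20_000 + i)
                v = r.normal(0, 1, (2, 3, 6))
                v[1] += effect
                res = two_way_anova(factorial_dataset(v))
                rej += res.effects["genotype"]["p"] < 0.05
            powers.append(rej / 100)
        assert powers[0] < powers[1] <= powers[2]

    def test_one_way_variant_runs_with_pooled_residual(self, rng):
        v = rng.normal(10, 2, (2, 3, 4))
        ds = factorial_dataset(v)
        res = one_way_anova(ds)
        assert res.effects["group"]["df_num"] == 5
        pw = sidak_pairwise(ds, res)
        assert set(pw) == {"2W", "4W", "8W"}


class TestSidak:
    def test_closed_form_values(self):
        assert sidak_adjust(0.0, 3) == 0.0
        assert sidak_adjust(0.05, 3) == pytest.approx(1 - 0.95**3)
        assert sidak_adjust(0.05, 3) == pytest.approx(0.142625)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.floats(0, 1), st.integers(1, 6))
    def test_adjusted_p_at_least_raw(self, p, m):
        adj = sidak_adjust(p, m)
        assert adj >= p - 1e-12
        assert 0 <= adj <= 1

    def test_pairwise_uses_pooled_residual_df(self, rng):
        v = rng.normal(10, 2, (2, 3, 4))
        ds = factorial_dataset(v)
        res = two_way_anova(ds)
        pw = sidak_pairwise(ds, res)
        for age, d in pw.items():
            assert d["df"] == res.residual_df
            assert d["p_adj"] == pytest.approx(sidak_adjust(d["p_raw"], 3))


class TestGeometricMean:
    def test_constant_values_collapse_interval(self):
        gm, lo, hi = geometric_mean_ci([3.0, 3.0, 3.0])
        assert gm == lo == hi == pytest.approx(3.0)

    def test_log_symmetric_values(self):
        gm, lo, hi = geometric_mean_ci([1.0, 10.0, 100.0])
        assert gm == pytest.approx(10.0)
        assert lo < gm < hi

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            geometric_mean_ci([1.0, -2.0])

    def test_ci_coverage_near_95pct(self):
        true_gm = 10 ** 0.5
        covered = 0
        reps = 300
        for i in range(reps):
            r = np.random.default_rng(30_000 + i)
            x = 10 ** r.normal(0.5, 0.4, 10)
            _, lo, hi = geometric_mean_ci(x)
            covered += lo <= true_gm <= hi
        assert 0.92 <= covered / reps <= 0.98
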