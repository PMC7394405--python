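import numpy as np
import pandas as pd
import pytest

from grazekit.core_io import SchemaError
from grazekit.stats_compare import (
    gamma_glm_compare, glm_table, greenness_diet_proportions,
    pairwise_contrasts, pool_groups,
)


def gamma_groups(rng, means, shape=8.0, n=50):
    values, groups = [], []
    for label, mean in means.items():
        values.append(rng.gamma(shape, mean / shape, size=n))
        groups.extend([label] * n)
    return np.concatenate(values), np.array(groups)


class TestGammaGlmCompare:
    def test_identical_groups_are_null(self, rng):
        y = rng.gamma(5.0, 2.0, size=40)
        values = np.concatenate([y, y])
        groups = np.array(["a"] * 40 + ["b"] * 40)
        res = gamma_glm_compare(values, groups)
        assert res.lr_chisq == pytest.approx(0.0, abs=1e-8)
        assert res.p_value > 0.99

    def test_fitted_means_equal_sample_means(self, rng):
        values, groups = gamma_groups(rng, {"a": 10.0, "b": 14.0, "c": 20.0})
        res = gamma_glm_compare(values, groups)
        for lev in res.levels:
            assert res.group_means[lev] == pytest.approx(
                values[groups == lev].mean(), abs=1e-8)

    def test_lr_invariant_under_rescaling(self, rng):
        values, groups = gamma_groups(rng, {"a": 10.0, "b": 15.0})
        r1 = gamma_glm_compare(values, groups)
        r2 = gamma_glm_compare(values * 37.5, groups)
        assert r1.lr_chisq == pytest.approx(r2.lr_chisq, rel=1e-6)
        assert r2.df == len(r2.levels) - 1 == 1

    def test_negative_values_point_to_shift_transform(self):
        with pytest.raises(SchemaError, match="shift_transform"):
            gamma_glm_compare([-0.1, 0.2, 0.3, 0.4],
                              ["a", "a", "b", "b"])

    def test_single_group_rejected(self):
        with pytest.raises(SchemaError, match="single group"):
            gamma_glm_compare([1.0, 2.0, 3.0], ["a", "a", "a"])

    def test_zero_values_offset_and_recorded(self, rng):
        values, groups = gamma_groups(rng, {"a": 1.0, "b": 1.5}, n=20)
        values[0] = 0.0
        res = gamma_glm_compare(values, groups)
        assert res.zero_offset > 0

    def test_power_on_separated_means(self):
        """Means 18 vs 23 at shape 8, n=200/group: p < 0.01 in >= 95% of
        100 replicate fits."""
        hits = 0
        rng = np.random.default_rng(42)
        for _ in range(100):
            values, groups = gamma_groups(rng, {"a": 18.0, "b": 23.0}, n=200)
            if gamma_glm_compare(values, groups).p_value < 0.01:
                hits += 1
        assert hits >= 95


class TestPairwiseContrasts:
    def test_identical_groups_all_null(self, rng):
        y = rng.gamma(6.0, 2.0, size=30)
        values = np.concatenate([y, y, y])
        groups = np.array(["a"] * 30 + ["b"] * 30 + ["c"] * 30)
        pw = pairwise_contrasts(gamma_glm_compare(values, groups))
        assert (pw["p_unadjusted"] > 0.9).all()

    def test_separated_group_detected(self, rng):
        values, groups = gamma_groups(
            rng, {"a": 10.0, "b": 10.0, "c": 20.0}, n=60)
        pw = pairwise_contrasts(gamma_glm_compare(values, groups))
        pw = pw.set_index(["level_a", "level_b"])
        assert pw.loc[("a", "b"), "p_unadjusted"] > 0.05
        assert pw.loc[("a", "c"), "p_unadjusted"] < 0.05
        assert pw.loc[("b", "c"), "p_unadjusted"] < 0.05

    def test_holm_dominates_unadjusted(self, rng):
        values, groups = gamma_groups(
            rng, {"a": 10.0, "b": 12.0, "c": 15.0, "d": 9.0}, n=25)
        pw = pairwise_contrasts(gamma_glm_compare(values, groups))
        assert (pw["p_holm"] >= pw["p_unadjusted"] - 1e-15).all()

    def test_two_groups_rejected(self, rng):
        values, groups = gamma_groups(rng, {"a": 10.0, "b": 12.0})
        with pytest.raises(SchemaError, match=">= 3 groups"):
            pairwise_contrasts(gamma_glm_compare(values, groups))


class TestPoolGroups:
    def test_pooled_then_two_level_comparison(self, rng):
        values, groups = gamma_groups(
            rng, {"low": 10.0, "mid": 10.0, "high": 10.0, "none": 14.0}, n=30)
        y, g = pool_groups(values, groups, ["low", "mid", "high"], "grazed")
        assert set(g) == {"grazed", "none"}
        res = gamma_glm_compare(y, g)
        assert res.df == 1

    def test_value_multiset_conserved(self, rng):
        values, groups = gamma_groups(rng, {"a": 5.0, "b": 6.0}, n=10)
        y, g = pool_groups(values, groups, ["a"], "pooled")
        assert np.array_equal(np.sort(y), np.sort(values))
        assert len(g) == len(groups)

    def test_pooling_single_group_is_identity_on_values(self, rng):
        values, groups = gamma_groups(rng, {"a": 5.0, "b": 6.0}, n=10)
        y, g = pool_groups(values, groups, ["a"], "a2")
        assert np.array_equal(y, values)

    def test_unknown_label_rejected(self):
        with pytest.raises(SchemaError, match="unknown group label"):
            pool_groups([1.0, 2.0], ["a", "b"], ["zz"], "p")


class TestGreennessDietProportions:
    def bites(self, rows):
        return pd.DataFrame(rows, columns=["camp_id", "greenness4"])

    def test_high_camp_pattern(self):
        df = self.bites([("high", "mainly green")] * 99
                        + [("high", "very green")])
        out = greenness_diet_proportions(df).set_index("greenness4")
        assert out.loc["mainly green", "proportion"] == pytest.approx(0.99)
        assert out.loc["very green", "proportion"] == pytest.approx(0.01)

    def test_all_very_green(self):
        df = self.bites([("c", "very green")] * 5)
        out = greenness_diet_proportions(df).set_index("greenness4")
        assert out.loc["mainly green", "proportion"] == 0.0
        assert out.loc["very green", "proportion"] == 1.0

    def test_brown_bites_excluded_and_sums_one(self):
        df = self.bites([("c", "very green"), ("c", "mainly green"),
                         ("c", "mainly brown")])
        out = greenness_diet_proportions(df)
        assert out["proportion"].sum() == pytest.approx(1.0)
        assert out["n_bites"].sum() == 2

    def test_no_green_bites_rejected(self):
        with pytest.raises(SchemaError, match="no bites"):
            greenness_diet_proportions(self.bites([("c", "very brown")]))


def test_glm_table_flattens_results(rng):
    values, groups = gamma_groups(rng, {"a": 10.0, "b": 12.0})
    out = glm_table([gamma_glm_compare(values, groups, response="height")])
    assert out.loc[0, "response"] == "height"
    assert {"lr_chisq", "p_value", "mean[a]", "mean[b]"} <= set(out.columns)
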