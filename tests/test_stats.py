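"""The statistical battery against hand oracles and printed values."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from walkmem import (
    GroupSummary,
    cohens_kappa,
    compare_groups,
    correlation_matrix,
    effect_size_d,
    icc_agreement,
    mixed_anova_2x2,
    pooled_t,
)
from walkmem.stats import CONTROL_MINUS_PATIENT, PATIENT_MINUS_CONTROL


def kappa_oracle(table):
    """Direct evaluation of kappa from a 2x2 confusion table."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    p_o = np.trace(table) / n
    p_e = float((table.sum(axis=1) / n) @ (table.sum(axis=0) / n))
    return (p_o - p_e) / (1 - p_e)


def icc2_oracle(ratings):
    """ICC(2,1) from the two-way mean-squares decomposition."""
    x = np.asarray(ratings, dtype=float)
    n, k = x.shape
    grand = x.mean()
    ms_rows = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    ms_cols = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    resid = x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True) + grand
    ms_err = (resid**2).sum() / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (
        ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
    )


def labels_from_table(table):
    l1, l2 = [], []
    for i, row in enumerate(table):
        for j, count in enumerate(row):
            l1 += [i] * count
            l2 += [j] * count
    return l1, l2


class TestPooledT:
    @pytest.mark.parametrize(
        "s1, s2, expected_t",
        [
            ((37.96, 9.25, 27), (38.89, 9.69, 27), -0.36),  # age
            ((14.67, 8.15, 27), (11.78, 7.81, 27), 1.33),  # ToM story errors
            ((11.65, 4.96, 27), (9.44, 4.98, 27), 1.63),  # mean story errors
        ],
    )
    def test_published_rows_recompute(self, s1, s2, expected_t):
        t, df, p, degenerate = pooled_t(GroupSummary(*s1), GroupSummary(*s2))
        assert round(t, 2) == expected_t
        assert df == 52
        assert 0 <= p <= 1 and not degenerate

    def test_equal_means_give_zero(self):
        t, _, p, _ = pooled_t(GroupSummary(5, 1, 10), GroupSummary(5, 2, 10))
        assert t == 0.0 and p == 1.0

    def test_direction_flips_sign(self):
        a, b = GroupSummary(6, 1, 10), GroupSummary(5, 1, 10)
        t1, _, _, _ = pooled_t(a, b, PATIENT_MINUS_CONTROL)
        t2, _, _, _ = pooled_t(a, b, CONTROL_MINUS_PATIENT)
        assert t1 == -t2

    def test_zero_variance_degenerate(self):
        t, _, p, degenerate = pooled_t(GroupSummary(5, 0, 10), GroupSummary(4, 0, 10))
        assert math.isinf(t) and t > 0 and p == 0.0 and degenerate
        with pytest.raises(ValueError):
            pooled_t(GroupSummary(5, 0, 10), GroupSummary(5, 0, 10))

    def test_raw_data_equals_exact_summaries(self, rng):
        x = rng.normal(10, 3, 27)
        y = rng.normal(11, 2, 27)
        cmp = compare_groups(x, y)
        t, df, p, _ = pooled_t(GroupSummary.of(x), GroupSummary.of(y))
        assert cmp.t == pytest.approx(t, abs=1e-10)
        assert cmp.p == pytest.approx(p, abs=1e-10)
        # and both agree with the reference implementation on raw data
        ref = sps.ttest_ind(x, y, equal_var=True)
        assert cmp.t == pytest.approx(ref.statistic, abs=1e-10)


class TestEffectSize:
    @pytest.mark.parametrize(
        "s1, s2, direction, expected_d",
        [
            ((25.17, 7.67, 27), (31.11, 5.33, 27), PATIENT_MINUS_CONTROL, -1.11),
            ((7.03, 2.71, 27), (5.23, 2.05, 27), CONTROL_MINUS_PATIENT, -0.88),
        ],
    )
    def test_published_glass_delta(self, s1, s2, direction, expected_d):
        d = effect_size_d(GroupSummary(*s1), GroupSummary(*s2), direction, "control_sd")
        assert round(d, 2) == expected_d

    def test_equal_means_give_zero(self):
        assert effect_size_d(GroupSummary(5, 1, 10), GroupSummary(5, 2, 10)) == 0.0

    def test_sign_agrees_with_t(self, rng):
        x, y = rng.normal(10, 3, 20), rng.normal(12, 3, 20)
        cmp = compare_groups(x, y)
        assert math.copysign(1, cmp.t) == math.copysign(1, cmp.d)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            effect_size_d(GroupSummary(5, 1, 10), GroupSummary(4, 0, 10))


class TestMixedAnova:
    def make_data(self, rng, n=20, group_effect=0.0, cat_effect=1.0):
        base = rng.normal(10, 2, 2 * n)
        shift = np.r_[np.zeros(n), np.full(n, group_effect)]
        return pd.DataFrame(
            {
                "participant_id": [f"s{i}" for i in range(2 * n)],
                "group": ["a"] * n + ["b"] * n,
                "perceptual": base + shift + cat_effect + rng.normal(0, 1, 2 * n),
                "action": base + shift + rng.normal(0, 1, 2 * n),
            }
        )

    def test_identical_values_give_zero_F(self):
        data = pd.DataFrame(
            {
                "participant_id": [f"s{i}" for i in range(8)],
                "group": ["a"] * 4 + ["b"] * 4,
                "perceptual": [3.0] * 8,
                "action": [3.0] * 8,
            }
        )
        res = mixed_anova_2x2(data)
        assert res.F_group == 0.0
        assert res.F_category == 0.0
        assert res.F_interaction == 0.0

    def test_category_F_equals_paired_t_squared(self, rng):
        """With two within levels, the condition F equals the squared
        paired t on the condition difference after removing the group
        effect (error df n-2)."""
        data = self.make_data(rng)
        res = mixed_anova_2x2(data)
        d = (data["perceptual"] - data["action"]).to_numpy()
        centered = d - np.repeat(
            [d[:20].mean(), d[20:].mean()], 20
        )  # remove group effect
        n = len(d)
        se = math.sqrt((centered**2).sum() / (n - 2) / n)
        t_paired = d.mean() / se
        assert res.F_category == pytest.approx(t_paired**2, abs=1e-8)
        assert res.df2 == n - 2

    def test_missing_condition_drops_participant(self, rng):
        data = self.make_data(rng, n=6)
        data.loc[0, "perceptual"] = np.nan
        res = mixed_anova_2x2(data)
        assert res.df2 == 9  # 11 participants remain, df2 = n - 2

    def test_category_effect_detected_null_effects_not(self):
        """Category shift of 2 units, no group effect: the category F is
        significant at alpha=.01 and the group/interaction Fs are not,
        in >=95% of replicates."""
        hits = 0
        for rep in range(200):
            rng = np.random.default_rng(3000 + rep)
            data = self.make_data(rng, n=27, group_effect=0.0, cat_effect=2.0)
            res = mixed_anova_2x2(data)
            hits += (
                res.p_category < 0.01
                and res.p_group > 0.01
                and res.p_interaction > 0.01
            )
        assert hits >= 190  # 95% of 200 replicates


class TestCorrelations:
    def test_exact_linear_relation(self, rng):
        x = rng.normal(size=20)
        df = pd.DataFrame({"x": x, "y": 2 * x + 1})
        out = correlation_matrix(df)
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_bonferroni_multiplies_and_caps(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        out = correlation_matrix(df, bonferroni_m=5)
        valid = out.dropna()
        assert np.allclose(valid["p_adj"], np.minimum(1.0, 5 * valid["p"]))
        assert (valid["p_adj"] >= valid["p"]).all()

    def test_null_false_positive_rate(self):
        """Independent Gaussian columns at n=27: |r| crosses the alpha=.05
        threshold in about 5% of cells."""
        rng = np.random.default_rng(99)
        hits = total = 0
        for _ in range(400):
            df = pd.DataFrame(rng.normal(size=(27, 3)), columns=list("abc"))
            out = correlation_matrix(df)
            hits += (out["p"] < 0.05).sum()
            total += len(out)
        assert 0.03 < hits / total < 0.07

    def test_zero_variance_column_gives_missing(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [2.0, 2, 2, 2]})
        out = correlation_matrix(df)
        assert math.isnan(out.loc[0, "r"])

    def test_pairwise_deletion(self):
        df = pd.DataFrame(
            {"x": [1.0, 2, 3, 4, np.nan], "y": [1.1, 2.2, 2.9, 4.1, 5.0]}
        )
        out = correlation_matrix(df)
        assert out.loc[0, "n"] == 4


class TestKappa:
    def test_identical_raters(self):
        assert cohens_kappa(list("ppaapp"), list("ppaapp")) == 1.0

    @pytest.mark.parametrize(
        "table, expected",
        [
            ([[45, 15], [25, 15]], 0.1304),
            ([[30, 30], [20, 20]], 0.0),  # independent margins
        ],
    )
    def test_confusion_tables_match_direct_formula(self, table, expected):
        l1, l2 = labels_from_table(table)
        k = cohens_kappa(l1, l2)
        assert k == pytest.approx(kappa_oracle(table), abs=1e-10)
        assert k == pytest.approx(expected, abs=1e-4)

    def test_symmetric_in_rater_exchange(self, rng):
        l1 = list(rng.integers(0, 3, 60))
        l2 = list(rng.integers(0, 3, 60))
        assert cohens_kappa(l1, l2) == pytest.approx(cohens_kappa(l2, l1))

    def test_constant_identical_raters(self):
        assert cohens_kappa(["p"] * 5, ["p"] * 5) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cohens_kappa([1, 2], [1])


class TestICC:
    TABLE = np.array([[9.0, 2.0], [4.5, 4.0], [6.0, 5.5], [8.0, 7.0], [7.0, 6.5]])

    def test_perfect_agreement(self):
        x = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        assert icc_agreement(x) == pytest.approx(1.0)

    def test_matches_mean_squares_oracle(self):
        assert icc_agreement(self.TABLE) == pytest.approx(
            icc2_oracle(self.TABLE), abs=1e-10
        )

    def test_constant_offset_penalized(self):
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        x = np.c_[base, base + 2.0]
        icc = icc_agreement(x)
        assert icc < 1.0
        assert icc == pytest.approx(icc2_oracle(x), abs=1e-10)

    def test_offset_not_penalized_under_consistency_form(self):
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        x = np.c_[base, base + 2.0]
        assert icc_agreement(x, form="icc3") == pytest.approx(1.0)

    def test_anticorrelated_raters_negative(self):
        base = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        x = np.c_[base, -base]
        assert icc_agreement(x) < 0
        assert icc_agreement(x) == pytest.approx(icc2_oracle(x), abs=1e-10)

    def test_symmetric_in_rater_exchange(self):
        swapped = self.TABLE[:, ::-1]
        assert icc_agreement(self.TABLE) == pytest.approx(
            icc_agreement(swapped), abs=1e-10
        )

    def test_constant_ratings_rejected(self):
        x = np.full((4, 2), 2.0)  # no variance anywhere: ICC is 0/0
        with pytest.raises(ValueError):
            icc_agreement(x)
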