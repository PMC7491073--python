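"""Group statistics: t-test families, corrections, two-way ANOVA."""

import numpy as np
import pandas as pd
import pytest

from tracemet.stats import (
    bonferroni_dunn_adjust,
    multiple_t_tests,
    sidak_adjust,
    summarize_groups,
    two_way_anova,
)


def tidy(groups: dict, stratum="s1"):
    rows = []
    for grp, values in groups.items():
        for v in values:
            rows.append({"group": grp, "metabolite": stratum, "value": v})
    return pd.DataFrame(rows)


class TestSummarize:
    def test_hand_arithmetic(self):
        df = tidy({"A": [1.0, 2.0, 3.0]})
        out = summarize_groups(df, "value", ["group"])
        assert out["mean"].iloc[0] == pytest.approx(2.0)
        assert out["sem"].iloc[0] == pytest.approx(1.0 / np.sqrt(3), abs=1e-3)
        assert out["n"].iloc[0] == 3

    def test_single_value_sem_missing(self):
        out = summarize_groups(tidy({"A": [4.0]}), "value", ["group"])
        assert out["mean"].iloc[0] == 4.0
        assert np.isnan(out["sem"].iloc[0])

    def test_noiseless_synthetic_summary_equals_truth(self):
        df = tidy({"A": [7.5] * 4})
        out = summarize_groups(df, "value", ["group"])
        assert out["mean"].iloc[0] == 7.5
        assert out["sem"].iloc[0] == 0.0


class TestAdjustments:
    def test_bonferroni_dunn_multiplies_and_caps(self):
        assert bonferroni_dunn_adjust(0.01, 2) == pytest.approx(0.02)
        assert bonferroni_dunn_adjust(0.4, 2) == pytest.approx(0.8)
        assert bonferroni_dunn_adjust(0.7, 3) == 1.0

    def test_sidak_identity_at_m1(self):
        assert sidak_adjust(0.037, 1) == pytest.approx(0.037)

    @pytest.mark.parametrize("p", [0.001, 0.01, 0.05, 0.2])
    @pytest.mark.parametrize("m", [2, 5, 9])
    def test_sidak_below_bonferroni_and_monotone(self, p, m):
        assert sidak_adjust(p, m) <= bonferroni_dunn_adjust(p, m)
        assert sidak_adjust(p, m) >= p


class TestMultipleTTests:
    def test_identical_groups_p_one(self):
        df = tidy({"A": [1.0, 2.0, 3.0], "B": [1.0, 2.0, 3.0]})
        out = multiple_t_tests(df, strata=["metabolite"])
        assert out["t"].iloc[0] == pytest.approx(0.0)
        assert out["raw_p"].iloc[0] == pytest.approx(1.0)
        assert out["adjusted_p"].iloc[0] == pytest.approx(1.0)

    def test_family_multiplication(self):
        rng = np.random.default_rng(0)
        frames = []
        for s, shift in (("m1", 2.0), ("m2", 0.0)):
            frames.append(
                pd.DataFrame(
                    {
                        "group": ["A"] * 6 + ["B"] * 6,
                        "metabolite": s,
                        "value": np.r_[rng.normal(0, 1, 6) + shift, rng.normal(0, 1, 6)],
                    }
                )
            )
        out = multiple_t_tests(pd.concat(frames), strata=["metabolite"])
        assert (out["family_size"] == 2).all()
        np.testing.assert_allclose(out["adjusted_p"], np.minimum(1, out["raw_p"] * 2))

    def test_pooled_variance_matches_scipy(self):
        import scipy.stats

        a = [1.2, 1.9, 2.3, 1.7]
        b = [2.8, 3.1, 2.2, 3.3]
        df = tidy({"A": a, "B": b})
        out = multiple_t_tests(df, strata=["metabolite"])
        ref = scipy.stats.ttest_ind(a, b, equal_var=True)
        assert out["t"].iloc[0] == pytest.approx(ref.statistic)
        assert out["raw_p"].iloc[0] == pytest.approx(ref.pvalue)

    def test_degenerate_stratum_skipped_with_warning(self):
        df = pd.concat(
            [tidy({"A": [1.0, 2.0], "B": [2.0, 3.0]}, "ok"), tidy({"A": [1.0], "B": [2.0, 3.0]}, "thin")]
        )
        with pytest.warns(UserWarning, match="thin"):
            out = multiple_t_tests(df, strata=["metabolite"])
        assert list(out["metabolite"]) == ["ok"]
        assert (out["family_size"] == 1).all()

    def test_direction_matches_mean_difference(self):
        df = tidy({"A": [5.0, 6.0, 7.0], "B": [1.0, 2.0, 3.0]})
        out = multiple_t_tests(df, strata=["metabolite"], groups=("A", "B"))
        assert out["direction"].iloc[0] == "a>b"

    def test_family_wise_error_controlled_under_null(self):
        """Bonferroni-Dunn FWER <= alpha + 2 MC-SE in a 9-stratum null
        simulation (800 seeded repetitions, lognormal measurement noise)."""
        rng = np.random.default_rng(99)
        n_rep, m, n, alpha = 800, 9, 6, 0.05
        truth = np.linspace(5.0, 45.0, m)
        false_positives = 0
        for _ in range(n_rep):
            rows = []
            for j in range(m):
                for grp in ("A", "B"):
                    vals = truth[j] * rng.lognormal(0, 0.05, n)
                    rows += [{"group": grp, "metabolite": f"m{j}", "value": v} for v in vals]
            out = multiple_t_tests(pd.DataFrame(rows), strata=["metabolite"], alpha=alpha)
            false_positives += bool(out["significant"].any())
        fwer = false_positives / n_rep
        mc_se = np.sqrt(alpha * (1 - alpha) / n_rep)
        assert fwer <= alpha + 2 * mc_se


def brute_force_two_way_ss(df, value, fa, fb):
    """Independent SS decomposition from cell/marginal means (balanced design)."""
    y = df[value].to_numpy(dtype=float)
    grand = y.mean()
    levels_a = sorted(df[fa].unique())
    levels_b = sorted(df[fb].unique())
    r = len(df) // (len(levels_a) * len(levels_b))
    mean_a = {a: df[df[fa] == a][value].mean() for a in levels_a}
    mean_b = {b: df[df[fb] == b][value].mean() for b in levels_b}
    cell = {
        (a, b): df[(df[fa] == a) & (df[fb] == b)][value].mean()
        for a in levels_a
        for b in levels_b
    }
    ss_a = len(levels_b) * r * sum((mean_a[a] - grand) ** 2 for a in levels_a)
    ss_b = len(levels_a) * r * sum((mean_b[b] - grand) ** 2 for b in levels_b)
    ss_ab = r * sum(
        (cell[(a, b)] - mean_a[a] - mean_b[b] + grand) ** 2
        for a in levels_a
        for b in levels_b
    )
    ss_resid = sum(
        (row[value] - cell[(row[fa], row[fb])]) ** 2 for _, row in df.iterrows()
    )
    return ss_a, ss_b, ss_ab, ss_resid


class TestTwoWayAnova:
    @pytest.fixture
    def balanced_2x2(self):
        rng = np.random.default_rng(7)
        rows = []
        for a, ea in (("g1", 0.0), ("g2", 1.5)):
            for b, eb in (("x", 0.0), ("y", 0.8)):
                interaction = 0.5 if (a, b) == ("g2", "y") else 0.0
                for _ in range(5):
                    rows.append(
                        {"group": a, "iso": b, "value": ea + eb + interaction + rng.normal(0, 1)}
                    )
        return pd.DataFrame(rows)

    def test_ss_decomposition_matches_brute_force(self, balanced_2x2):
        anova, _ = two_way_anova(balanced_2x2, "value", "group", "iso")
        ss_a, ss_b, ss_ab, ss_resid = brute_force_two_way_ss(balanced_2x2, "value", "group", "iso")
        assert anova.loc["group", "sum_sq"] == pytest.approx(ss_a, abs=1e-9)
        assert anova.loc["iso", "sum_sq"] == pytest.approx(ss_b, abs=1e-9)
        assert anova.loc["group:iso", "sum_sq"] == pytest.approx(ss_ab, abs=1e-9)
        assert anova.loc["residual", "sum_sq"] == pytest.approx(ss_resid, abs=1e-9)

    def test_ss_terms_sum_to_total(self, balanced_2x2):
        anova, _ = two_way_anova(balanced_2x2, "value", "group", "iso")
        y = balanced_2x2["value"].to_numpy()
        total = ((y - y.mean()) ** 2).sum()
        assert anova["sum_sq"].sum() == pytest.approx(total, abs=1e-9)

    def test_f_pvalues_match_distribution_function(self, balanced_2x2):
        import scipy.stats

        anova, _ = two_way_anova(balanced_2x2, "value", "group", "iso")
        mse = anova.loc["residual", "sum_sq"] / anova.loc["residual", "df"]
        for term in ("group", "iso", "group:iso"):
            f = (anova.loc[term, "sum_sq"] / anova.loc[term, "df"]) / mse
            p = scipy.stats.f.sf(f, anova.loc[term, "df"], anova.loc["residual", "df"])
            assert anova.loc[term, "F"] == pytest.approx(f, rel=1e-9)
            assert anova.loc[term, "PR(>F)"] == pytest.approx(p, rel=1e-9)

    def test_pairwise_sidak_adjustment(self, balanced_2x2):
        _, pairwise = two_way_anova(balanced_2x2, "value", "group", "iso")
        assert len(pairwise) == 2
        np.testing.assert_allclose(
            pairwise["adjusted_p"], 1 - (1 - pairwise["raw_p"]) ** 2
        )

    def test_single_level_factor_rejected(self):
        df = pd.DataFrame({"group": ["A"] * 4, "iso": ["x", "x", "y", "y"], "value": [1, 2, 3, 4]})
        with pytest.raises(ValueError, match="single level"):
            two_way_anova(df, "value", "group", "iso")

    def test_zero_variance_flagged_not_divided(self):
        df = pd.DataFrame(
            {
                "group": ["A", "A", "B", "B"] * 2,
                "iso": ["x"] * 4 + ["y"] * 4,
                "value": [1.0] * 8,
            }
        )
        anova, pairwise = two_way_anova(df, "value", "group", "iso")
        assert np.isnan(anova["F"]).all()
        assert pairwise["degenerate"].all()
        assert not pairwise["significant"].any()
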