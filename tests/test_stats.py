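"""Statistics pipeline vs independent oracles (brute force, scipy, statsmodels)."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from marrow_reservoir import (
    DegenerateDataError,
    ValidationError,
    analyze_cohort,
    dunnett,
    normalize_mfi,
    one_way_anova,
    significance_stars,
    t_test,
    tukey_hsd,
)
from marrow_reservoir.cohort import CohortConfig, generate_cohort

VALUES = np.array([1.0, 2.0, 3.0, 2.0, 3.0, 4.0, 6.0, 7.0, 8.0])
LABELS = np.array(["a"] * 3 + ["b"] * 3 + ["c"] * 3)


def brute_force_F(values, labels):
    """Independent sum-of-squares decomposition via explicit loops."""
    groups = {}
    for v, lab in zip(values, labels):
        groups.setdefault(lab, []).append(v)
    grand = sum(values) / len(values)
    ssb = ssw = 0.0
    for obs in groups.values():
        mean = sum(obs) / len(obs)
        ssb += len(obs) * (mean - grand) ** 2
        for v in obs:
            ssw += (v - mean) ** 2
    df_b = len(groups) - 1
    df_w = len(values) - len(groups)
    return (ssb / df_b) / (ssw / df_w)


class TestAnova:
    def test_matches_brute_force_decomposition(self):
        res = one_way_anova(VALUES, LABELS)
        assert res.F == pytest.approx(brute_force_F(VALUES, LABELS), abs=1e-12)
        assert res.F == pytest.approx(21.0, abs=1e-12)
        assert (res.df_between, res.df_within) == (2, 6)

    def test_matches_scipy_f_oneway(self, rng):
        values = rng.normal(size=40)
        labels = np.repeat(["w", "x", "y", "z"], 10)
        res = one_way_anova(values, labels)
        ref = sps.f_oneway(*(values[labels == g] for g in "wxyz"))
        assert res.F == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_two_groups_equals_squared_pooled_t(self, rng):
        a, b = rng.normal(size=8), rng.normal(1.0, 1.0, size=11)
        values = np.concatenate([a, b])
        labels = np.array(["a"] * 8 + ["b"] * 11)
        res = one_way_anova(values, labels)
        t = t_test(a, b, variant="pooled")
        assert res.F == pytest.approx(t.t**2, rel=1e-12)

    def test_group_renaming_leaves_F_unchanged(self):
        renamed = np.array([{"a": "z", "b": "q", "c": "m"}[x] for x in LABELS])
        assert one_way_anova(VALUES, renamed).F == one_way_anova(VALUES, LABELS).F

    @given(shift=st.floats(-50, 50), scale=st.floats(0.1, 20))
    def test_affine_invariance(self, shift, scale):
        res0 = one_way_anova(VALUES, LABELS)
        res1 = one_way_anova(VALUES * scale + shift, LABELS)
        assert res1.F == pytest.approx(res0.F, rel=1e-9)

    def test_singleton_group_rejected(self):
        with pytest.raises(ValidationError, match="fewer than 2"):
            one_way_anova([1.0, 2.0, 3.0], ["a", "a", "b"])

    def test_zero_within_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            one_way_anova([1.0, 1.0, 2.0, 2.0], ["a", "a", "b", "b"])


class TestTukey:
    def test_two_groups_reduce_to_pooled_t(self, rng):
        a, b = rng.normal(size=9), rng.normal(0.8, 1.0, size=9)
        values, labels = np.concatenate([a, b]), np.array(["a"] * 9 + ["b"] * 9)
        res = tukey_hsd(values, labels, n_mc=200_000, seed=1)
        t = t_test(a, b, variant="pooled")
        assert len(res) == 1
        assert res[0].statistic == pytest.approx(np.sqrt(2) * abs(t.t), rel=1e-12)
        assert res[0].p_adj == pytest.approx(t.p, abs=0.005)

    def test_agrees_with_studentized_range_oracle(self, rng):
        # scipy's closed-form studentized-range implementation is the
        # independent reference for the balanced design
        groups = [rng.normal(mu, 1.0, size=8) for mu in (0.0, 0.5, 1.0, 0.2)]
        values = np.concatenate(groups)
        labels = np.repeat(list("abcd"), 8)
        ours = {r.pair: r.p_adj for r in tukey_hsd(values, labels, n_mc=400_000, seed=2)}
        ref = sps.tukey_hsd(*groups)
        names = "abcd"
        for i in range(4):
            for j in range(i + 1, 4):
                assert ours[(names[i], names[j])] == pytest.approx(
                    ref.pvalue[i, j], abs=0.005
                )

    def test_equal_group_means_are_never_flagged(self):
        values = np.array([1.0, 2.0, 3.0] * 3)
        labels = np.repeat(list("abc"), 3)
        for res in tukey_hsd(values, labels, n_mc=100_000, seed=3):
            assert res.p_adj > 0.99

    def test_adjusted_p_not_below_unadjusted(self, rng):
        values = rng.normal(size=24)
        labels = np.repeat(list("abc"), 8)
        groups = {g: values[labels == g] for g in "abc"}
        for res in tukey_hsd(values, labels, n_mc=200_000, seed=4):
            raw = t_test(groups[res.pair[0]], groups[res.pair[1]], variant="pooled").p
            assert res.p_adj >= raw - 0.01

    def test_reproducible_given_seed(self):
        values = np.arange(12.0) + np.array([0, 1, 0, 1] * 3)
        labels = np.repeat(list("abc"), 4)
        first = tukey_hsd(values, labels, n_mc=50_000, seed=9)
        second = tukey_hsd(values, labels, n_mc=50_000, seed=9)
        assert [r.p_adj for r in first] == [r.p_adj for r in second]


class TestDunnett:
    def test_single_treatment_reduces_to_pooled_t(self, rng):
        ctrl, treat = rng.normal(size=10), rng.normal(0.7, 1.0, size=12)
        values = np.concatenate([ctrl, treat])
        labels = np.array(["ctrl"] * 10 + ["t1"] * 12)
        res = dunnett(values, labels, "ctrl", n_mc=200_000, seed=5)
        t = t_test(treat, ctrl, variant="pooled")
        assert len(res) == 1
        assert res[0].statistic == pytest.approx(t.t, rel=1e-12)
        assert res[0].p_adj == pytest.approx(t.p, abs=0.005)

    def test_agrees_with_scipy_dunnett(self, rng):
        ctrl = rng.normal(size=10)
        treats = [rng.normal(mu, 1.0, size=10) for mu in (0.4, 0.9, -0.3)]
        values = np.concatenate([ctrl] + treats)
        labels = np.array(["ctrl"] * 10 + ["t1"] * 10 + ["t2"] * 10 + ["t3"] * 10)
        ours = dunnett(values, labels, "ctrl", n_mc=400_000, seed=6)
        ref = sps.dunnett(*treats, control=ctrl, random_state=np.random.default_rng(0))
        for our, ref_p in zip(ours, ref.pvalue):
            assert our.p_adj == pytest.approx(ref_p, abs=0.01)

    def test_adding_irrelevant_group_never_helps(self, rng):
        ctrl, treat = rng.normal(size=10), rng.normal(0.9, 1.0, size=10)
        extra = rng.normal(size=10)
        v2 = np.concatenate([ctrl, treat])
        l2 = np.array(["ctrl"] * 10 + ["t1"] * 10)
        v3 = np.concatenate([ctrl, treat, extra])
        l3 = np.array(["ctrl"] * 10 + ["t1"] * 10 + ["t2"] * 10)
        p2 = dunnett(v2, l2, "ctrl", n_mc=200_000, seed=7)[0].p_adj
        p3 = next(
            r.p_adj for r in dunnett(v3, l3, "ctrl", n_mc=200_000, seed=7) if r.pair[0] == "t1"
        )
        assert p3 >= p2 - 0.01  # family-wise correction is monotone in family size

    def test_missing_control_rejected(self):
        with pytest.raises(ValidationError, match="control"):
            dunnett([1.0, 2.0, 3.0, 4.0], ["a", "a", "b", "b"], "zz")


class TestTTest:
    def test_identical_samples_give_t_zero_p_one(self):
        res = t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], variant="pooled")
        assert res.t == 0.0 and res.p == pytest.approx(1.0)

    def test_hand_computed_pooled_example(self):
        # means 2.5 vs 4.5, pooled var 5/3 -> t = -2 * sqrt(6/5), df = 6
        res = t_test([1.0, 2.0, 3.0, 4.0], [3.0, 4.0, 5.0, 6.0], variant="pooled")
        assert res.t == pytest.approx(-2.1908902300206643, abs=1e-12)
        assert res.df == 6

    @pytest.mark.parametrize("variant,scipy_kwargs", [
        ("pooled", {"equal_var": True}),
        ("welch", {"equal_var": False}),
    ])
    def test_matches_scipy(self, rng, variant, scipy_kwargs):
        a, b = rng.normal(size=9), rng.normal(0.5, 2.0, size=14)
        res = t_test(a, b, variant=variant)
        ref = sps.ttest_ind(a, b, **scipy_kwargs)
        assert res.t == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_paired_matches_scipy(self, rng):
        a = rng.normal(size=12)
        b = a + rng.normal(0.3, 0.5, size=12)
        res = t_test(a, b, variant="paired")
        ref = sps.ttest_rel(a, b)
        assert res.t == pytest.approx(ref.statistic, rel=1e-12)

    def test_welch_df_never_exceeds_pooled(self, rng):
        a, b = rng.normal(size=8, scale=1.0), rng.normal(size=15, scale=3.0)
        pooled = t_test(a, b, variant="pooled")
        welch = t_test(a, b, variant="welch")
        assert welch.df <= pooled.df
        # equality holds when variances and sizes coincide
        sym = t_test(a, a + 1.0, variant="welch")
        assert sym.df == pytest.approx(2 * len(a) - 2)

    def test_degenerate_equal_constant_samples_rejected(self):
        with pytest.raises(DegenerateDataError):
            t_test([2.0, 2.0, 2.0], [2.0, 2.0, 2.0], variant="pooled")


class TestNormalizeMfi:
    def test_direct_fold_change(self):
        assert normalize_mfi(200.0, 100.0) == 2.0
        assert normalize_mfi(150.0, 150.0) == 1.0

    @given(x=st.floats(0.01, 1e4), y=st.floats(0.01, 1e4))
    def test_reciprocal_product_is_one(self, x, y):
        assert normalize_mfi(x, y) * normalize_mfi(y, x) == pytest.approx(1.0, rel=1e-12)

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValidationError, match="unstimulated"):
            normalize_mfi(100.0, 0.0)


class TestStars:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.2, "ns"), (0.04, "*"), (0.009, "**"), (0.0009, "***"), (0.00009, "****")],
    )
    def test_threshold_mapping(self, p, expected):
        assert significance_stars(p) == expected


class TestAnalyzeCohort:
    def test_empty_plan_yields_empty_table(self, default_cohort):
        table = analyze_cohort(default_cohort, plan=[])
        assert len(table) == 0
        assert list(table.columns) == [
            "endpoint", "test", "groups", "statistic", "df", "p", "p_adj", "stars",
        ]

    def test_unknown_endpoint_rejected(self, default_cohort):
        with pytest.raises(ValidationError, match="unknown endpoint"):
            analyze_cohort(default_cohort, plan=[{"endpoint": "nope", "test": "tukey"}])

    def test_default_plan_produces_expected_rows(self, default_cohort):
        table = analyze_cohort(default_cohort, n_mc=20_000, seed=1)
        # 10 tukey endpoints: 1 anova + 6 pairwise rows each; 2 ttest blocks of 4 groups
        assert len(table) == 10 * 7 + 2 * 4
        anova_rows = table[table["test"] == "anova"]
        assert set(anova_rows["endpoint"]) >= {"classical_pct", "chemo_basal"}

    def test_configured_effects_are_detected_reliably(self):
        # under the default (study-anchored) group separation, the classical
        # subset ANOVA should be significant in nearly every replicate
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            cohort = generate_cohort(seed=seed)
            from marrow_reservoir import one_way_anova

            res = one_way_anova(
                cohort["classical_pct"].to_numpy(), cohort["group"].to_numpy()
            )
            hits += res.p < 0.05
        assert hits / n_rep >= 0.95

    def test_within_group_stimulation_contrast(self, default_cohort):
        table = analyze_cohort(
            default_cohort,
            plan=[{"endpoint": "ros_ecoli_pct", "test": "ttest", "baseline": "ros_control_pct"}],
        )
        assert len(table) == 4
        # E. coli drives responders from ~2.5% to >=40% in every group
        assert (table["p"] < 1e-4).all()

    def test_dunnett_plan_entry(self, default_cohort):
        table = analyze_cohort(
            default_cohort,
            plan=[{"endpoint": "chemo_basal", "test": "dunnett", "control": "HC"}],
            n_mc=20_000,
        )
        assert (table["test"] == "dunnett").sum() == 3
        assert all(" vs HC" in g for g in table[table["test"] == "dunnett"]["groups"])
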