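"""Nonparametric test battery: U, H, Holm, KS screen, kappa."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from efos.stats import (
    cohen_kappa,
    compare_transitions,
    fos_category_comparison,
    holm_adjust,
    kruskal_wallis_eps2,
    mann_whitney_r,
    normality_screen,
    pairwise_fos_comparisons,
)


def exact_mwu_p(a, b):
    """Brute-force two-sided p by enumerating all group assignments."""
    pooled = list(a) + list(b)
    n_a = len(a)

    def u_stat(ix):
        ga = [pooled[i] for i in ix]
        gb = [pooled[i] for i in range(len(pooled)) if i not in ix]
        return sum(1 for x in ga for y in gb if x > y) + 0.5 * sum(
            1 for x in ga for y in gb if x == y
        )

    observed = u_stat(tuple(range(n_a)))
    mu = n_a * (len(pooled) - n_a) / 2
    us = [u_stat(ix) for ix in itertools.combinations(range(len(pooled)), n_a)]
    return sum(1 for u in us if abs(u - mu) >= abs(observed - mu) - 1e-12) / len(us)


class TestMannWhitney:
    def test_exact_p_matches_enumeration_oracle(self):
        a, b = [1, 2, 3], [4, 5, 6]
        assert exact_mwu_p(a, b) == pytest.approx(0.10)
        res = mann_whitney_r(a, b, method="exact")
        assert res.p_value == pytest.approx(0.10)
        assert res.statistic == 0.0  # U of the first group

    def test_identical_groups_have_zero_effect(self):
        res = mann_whitney_r([5, 5], [5, 5])
        assert res.z_value == 0.0 and res.effect_size == 0.0
        assert res.p_value == 1.0

    def test_u_identity(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=13), rng.normal(size=9)
        u_a = mann_whitney_r(a, b).statistic
        u_b = mann_whitney_r(b, a).statistic
        assert u_a + u_b == pytest.approx(len(a) * len(b))

    def test_effect_size_is_abs_z_over_sqrt_n(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=20), rng.normal(1.0, size=25)
        res = mann_whitney_r(a, b)
        assert res.effect_size == pytest.approx(abs(res.z_value) / np.sqrt(45))
        assert 0 <= res.effect_size <= 1

    def test_missing_values_dropped_and_empty_group_rejected(self):
        res = mann_whitney_r([1.0, np.nan, 2.0], [3.0, 4.0])
        assert res.n_per_group == (2, 2)
        with pytest.raises(ValueError, match="no defined values"):
            mann_whitney_r([np.nan], [1.0, 2.0])

    def test_type_one_error_near_nominal_level(self):
        """Null rejection rate at alpha = .05, n = 100/group, 2000 reps."""
        rng = np.random.default_rng(2026)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            a = rng.normal(size=100)
            b = rng.normal(size=100)
            if mann_whitney_r(a, b).p_value < 0.05:
                rejections += 1
        assert 0.035 <= rejections / reps <= 0.065

    def test_power_against_a_transition_probability_shift(self):
        """A generating-matrix shift of the size the simulator defaults to
        is detected with power > 0.9 at ~100 units per group."""
        from efos import SimulationConfig, load_reference_matrix, renormalize_rows
        from efos.simulate import apply_group_effects

        base = renormalize_rows(load_reference_matrix())
        shifted = apply_group_effects(base, {("DEF", "FOS#3"): ("mul", 1.2)})
        p0 = base.cell("DEF", "FOS#3")
        p1 = shifted.cell("DEF", "FOS#3")
        rng = np.random.default_rng(17)
        m = 90  # DEF shots per unit, ~ one match's worth
        detected = 0
        reps = 200
        for _ in range(reps):
            a = rng.binomial(m, p0, size=100) / m
            b = rng.binomial(m, p1, size=100) / m
            if mann_whitney_r(a, b).p_value < 0.05:
                detected += 1
        assert detected / reps > 0.9


class TestKruskalWallis:
    def test_hand_rank_sum_oracle(self):
        """H for {1,2},{3,4},{5,6}: ranks 1..6, rank sums 3/7/11,
        H = 12/(6*7) * (9+49+121)/2 - 21 = 32/7."""
        res = kruskal_wallis_eps2({"a": [1, 2], "b": [3, 4], "c": [5, 6]})
        assert res.statistic == pytest.approx(32 / 7)
        assert res.effect_size == pytest.approx((32 / 7) * 7 / 35)

    def test_identical_constant_groups(self):
        res = kruskal_wallis_eps2({"a": [2, 2], "b": [2, 2], "c": [2, 2]})
        assert res.statistic == 0.0 and res.effect_size == 0.0

    def test_eps2_bounded_by_one(self):
        rng = np.random.default_rng(9)
        groups = {k: rng.normal(loc=i * 3, size=30) for i, k in enumerate("abc")}
        res = kruskal_wallis_eps2(groups)
        assert 0 <= res.effect_size <= 1


class TestHolm:
    def test_step_down_recurrence(self):
        # sorted: .01*3=.03; .03*2=.06; .04*1=.04 -> monotone max = .06
        assert holm_adjust([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.06, 0.06])

    def test_single_value_capped(self):
        assert holm_adjust([1.0]) == [1.0]

    def test_never_decreases_and_preserves_order(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=12)
        adj = np.array(holm_adjust(p))
        assert (adj >= p - 1e-15).all()
        # ranking preserved: sorting by raw p sorts adjusted p too
        assert (np.diff(adj[np.argsort(p)]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])


class TestPairwise:
    def test_identical_groups_never_flagged(self):
        g = {"2": [1, 2, 3, 4], "3": [1, 2, 3, 4], "GE4": [1, 2, 3, 4]}
        out = pairwise_fos_comparisons(g)
        assert not out["significant"].any()

    def test_one_shifted_group_flagged_against_both_others(self):
        rng = np.random.default_rng(21)
        g = {
            "2": list(rng.normal(0, 1, 105)),
            "3": list(rng.normal(0, 1, 105)),
            "GE4": list(rng.normal(2.0, 1, 105)),
        }
        out = pairwise_fos_comparisons(g)
        flagged = set(out.loc[out["significant"], "pair"])
        assert flagged == {"2 vs GE4", "3 vs GE4"}

    def test_adjusted_p_at_least_raw(self):
        rng = np.random.default_rng(22)
        g = {k: list(rng.normal(i, 1, 20)) for i, k in enumerate(["2", "3", "GE4"])}
        for method in ("mwu", "dunn"):
            out = pairwise_fos_comparisons(g, method=method)
            assert (out["p_holm"] >= out["p_raw"] - 1e-15).all()

    def test_requires_three_groups(self):
        with pytest.raises(ValueError):
            pairwise_fos_comparisons({"a": [1], "b": [2]})


class TestNormalityScreen:
    def test_bimodal_mixture_flagged(self):
        rng = np.random.default_rng(7)
        values = np.concatenate([np.zeros(100), np.ones(100)]) + rng.normal(
            0, 0.01, 200
        )
        out = normality_screen({"v": values})
        assert bool(out.loc[0, "non_normal"])

    def test_gaussian_rarely_flagged(self):
        rng = np.random.default_rng(8)
        flags = []
        for _ in range(40):
            out = normality_screen({"v": rng.normal(size=200)})
            flags.append(bool(out.loc[0, "non_normal"]))
        assert np.mean(flags) <= 0.10

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            normality_screen({"v": [1.0, 2.0]})

    def test_constant_input_flagged_degenerate(self):
        out = normality_screen({"v": [3.0] * 10})
        assert bool(out.loc[0, "degenerate"]) and bool(out.loc[0, "non_normal"])


class TestKappa:
    def test_perfect_agreement(self):
        res = cohen_kappa(["a", "b", "a"], ["a", "b", "a"])
        assert res.kappa == pytest.approx(1.0)

    def test_constructed_two_by_two_table(self):
        """45/5/5/45 table: p_o = .9, p_e = .5 -> kappa = .8."""
        a = ["x"] * 50 + ["y"] * 50
        b = ["x"] * 45 + ["y"] * 5 + ["x"] * 5 + ["y"] * 45
        res = cohen_kappa(a, b)
        assert res.kappa == pytest.approx(0.8)

    def test_independent_shuffles_give_near_zero(self):
        rng = np.random.default_rng(10)
        a = list(rng.choice(["x", "y", "z"], size=3000))
        b = list(rng.choice(["x", "y", "z"], size=3000))
        assert abs(cohen_kappa(a, b).kappa) < 0.05

    def test_constant_identical_raters_undefined(self):
        res = cohen_kappa(["a"] * 10, ["a"] * 10)
        assert res.kappa is None and not res.defined

    def test_invariant_to_label_renaming(self):
        a = ["a", "b", "b", "c", "a", "c", "b"]
        b = ["a", "b", "c", "c", "a", "a", "b"]
        ren = {"a": "Q", "b": "R", "c": "S"}
        k1 = cohen_kappa(a, b).kappa
        k2 = cohen_kappa([ren[x] for x in a], [ren[x] for x in b]).kappa
        assert k1 == pytest.approx(k2)


class TestGroupComparisonPipeline:
    def test_gender_shift_detected_in_transition_comparison(self):
        """A simulated upward shift of P(DEF -> FOS#3) for women's matches
        shows up with the right sign and a small p in the group table."""
        from efos import SimulationConfig, simulate_dataset

        ds = simulate_dataset(
            SimulationConfig(
                n_matches=60,
                rallies_per_match=90,
                seed=13,
                group_effects={("gender", "F"): {("DEF", "FOS#3"): ("mul", 1.25)}},
            )
        )
        table = compare_transitions(ds.records, "gender")
        row = table.set_index(["from_state", "to_state"]).loc[("DEF", "FOS#3")]
        assert row["mean_F"] > row["mean_M"]
        assert row["p_value"] < 0.05

    def test_category_comparison_shape_and_defaults(self, small_dataset):
        out = fos_category_comparison(small_dataset.records)
        assert set(out["from_state"]) == {"FOS", "FOS+1", "FOS+2", "FOS+3"}
        assert len(out) == 12
        assert ((out["eps2"] >= 0) & (out["eps2"] <= 1)).all()
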