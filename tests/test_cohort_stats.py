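"""Test dispatcher, Mann-Whitney, chi-square, Spearman, winsorising, FDR, RRB subtypes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from alphaconn import (
    bh_fdr,
    chi_square_2x2,
    choose_test,
    correlation_analysis,
    mann_whitney,
    mw_z_from_u,
    rrb_subtype_scores,
    spearman,
    winsorize_max,
)


class TestChooseTest:
    def test_normal_homoscedastic_data_mostly_gets_t_test(self):
        rng = np.random.default_rng(0)
        picks = [
            choose_test(rng.standard_normal(80), rng.standard_normal(80))
            for _ in range(100)
        ]
        # each of the three assumption tests rejects ~5% of the time under the null
        assert picks.count("t-test") >= 75

    def test_gross_outlier_forces_mann_whitney(self):
        rng = np.random.default_rng(1)
        a = np.append(rng.standard_normal(30), 1e6)
        b = rng.standard_normal(30)
        assert choose_test(a, b) == "mann-whitney"

    def test_constant_group_forces_mann_whitney_with_warning(self):
        with pytest.warns(UserWarning, match="constant group"):
            assert choose_test([1.0] * 5, [1.0, 2.0, 3.0, 4.0]) == "mann-whitney"

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            choose_test([1.0, 2.0], [1.0, 2.0, 3.0])


class TestMannWhitney:
    def test_small_sample_exact_p_by_enumeration(self):
        res = mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert res.value == 0.0
        assert res.p_mode == "exact"
        assert res.p == pytest.approx(1.0 / 3.0)

    def test_identical_groups_are_central(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        res = mann_whitney(vals, vals)
        assert res.value == pytest.approx(len(vals) ** 2 / 2)
        assert res.z == pytest.approx(0.0)

    def test_ties_fall_back_to_asymptotic_with_warning(self):
        with pytest.warns(UserWarning, match="ties"):
            res = mann_whitney([1.0, 2.0, 2.0], [2.0, 3.0], p_mode="exact")
        assert res.p_mode == "asymptotic"

    def test_large_product_uses_asymptotic(self):
        rng = np.random.default_rng(2)
        res = mann_whitney(rng.standard_normal(40), rng.standard_normal(40))
        assert res.p_mode == "asymptotic"

    @pytest.mark.parametrize(
        "u, n1, n2, z_expected, r_expected",
        [
            (104, 20, 13, -0.958, -0.17),
            (275, 47, 13, -0.547, -0.07),
            (125, 21, 13, -0.408, -0.07),
        ],
    )
    def test_normal_approximation_from_u(self, u, n1, n2, z_expected, r_expected):
        """Published group comparisons: z and r = z/sqrt(N) from U and group sizes."""
        z, r = mw_z_from_u(u, n1, n2)
        assert z == pytest.approx(z_expected, abs=5e-4)
        assert r == pytest.approx(r_expected, abs=5e-3)


class TestChiSquare:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ([[11, 9], [11, 2]], 3.11),   # LR vs HR-ASD male/female counts
            ([[22, 25], [11, 2]], 5.88),  # HR-TD vs HR-ASD
            ([[14, 7], [11, 2]], 1.33),   # HR-Atyp vs HR-ASD
            ([[10, 10], [10, 10]], 0.0),
        ],
    )
    def test_sex_distribution_tables(self, table, expected):
        assert chi_square_2x2(table).value == pytest.approx(expected, abs=5e-3)

    def test_invariant_under_transposition_and_swaps(self):
        t = np.array([[11, 9], [11, 2]])
        base = chi_square_2x2(t).value
        assert chi_square_2x2(t.T).value == pytest.approx(base)
        assert chi_square_2x2(t[::-1]).value == pytest.approx(base)
        assert chi_square_2x2(t[:, ::-1]).value == pytest.approx(base)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2([[0, 0], [5, 3]])


class TestSpearman:
    def test_monotone_extremes(self):
        x = [1.0, 2.0, 3.0, 5.0]
        assert spearman(x, [2.0, 7.0, 9.0, 11.0]).value == pytest.approx(1.0)
        assert spearman(x, [11.0, 9.0, 7.0, 2.0]).value == pytest.approx(-1.0)

    def test_hand_computed_rho(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) with sum(d^2) = 2
        assert spearman([1, 2, 3, 4], [1, 3, 2, 4]).value == pytest.approx(0.8)

    def test_pairwise_complete(self):
        res = spearman([1, 2, np.nan, 4, 5], [2, 4, 6, np.nan, 10])
        assert res.n1 == 3
        assert res.value == pytest.approx(1.0)

    def test_zero_rank_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestWinsorize:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([0.1, 0.2, 0.9], [0.1, 0.2, 0.2]),
            ([3.0, 3.0, 3.0], [3.0, 3.0, 3.0]),
            ([1.0, 3.0, 3.0], [1.0, 1.0, 1.0]),
        ],
    )
    def test_examples(self, values, expected):
        np.testing.assert_allclose(winsorize_max(values), expected)

    def test_input_not_mutated(self):
        x = np.array([0.1, 0.9])
        winsorize_max(x)
        assert x[1] == 0.9


class TestBHFDR:
    def test_hand_checked_step_up(self):
        reject, _ = bh_fdr([0.001, 0.008, 0.039, 0.041, 0.042, 0.06], q=0.05)
        assert reject.tolist() == [True, True, False, False, False, False]

    def test_degenerate_cases(self):
        assert not bh_fdr([1.0, 1.0, 1.0])[0].any()
        assert bh_fdr([0.04], q=0.05)[0].all()

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=8))
    def test_matches_step_up_definition(self, p_values):
        """BH agrees with the literal step-up rule for small families."""
        reject, _ = bh_fdr(p_values, q=0.05)
        p = np.asarray(p_values)
        m = len(p)
        order = np.argsort(p, kind="stable")
        k = 0
        for rank, idx in enumerate(order, start=1):
            if p[idx] <= rank * 0.05 / m:
                k = rank
        expected = np.zeros(m, dtype=bool)
        expected[order[:k]] = True
        assert reject.tolist() == expected.tolist()


class TestRRBSubtypes:
    def make_items(self):
        return pd.DataFrame(
            {"a": [1.0, 2.0], "b": [2.0, np.nan], "c": [0.0, 3.0]},
            index=["s0", "s1"],
        )

    def test_sums_and_missing_propagation(self):
        out = rrb_subtype_scores(self.make_items(), {"motor": ["a", "b"], "ci": ["c"]})
        assert out.loc["s0", "motor"] == 3.0
        assert np.isnan(out.loc["s1", "motor"])  # missing item -> missing subtype
        assert out.loc["s1", "ci"] == 3.0

    @pytest.mark.parametrize(
        "sets", [{"motor": []}, {"motor": ["zzz"]}, {"m1": ["a"], "m2": ["a"]}]
    )
    def test_invalid_item_sets_rejected(self, sets):
        with pytest.raises(ValueError):
            rrb_subtype_scores(self.make_items(), sets)

    def test_bundled_default_item_sets_are_disjoint_and_usable(self):
        from alphaconn import default_rrb_item_sets

        sets = default_rrb_item_sets()
        assert set(sets) == {
            "repetitive_motor_behaviours",
            "insistence_on_sameness",
            "circumscribed_interests",
        }
        items = [i for v in sets.values() for i in v]
        assert len(items) == len(set(items))
        table = pd.DataFrame([np.ones(len(items))], columns=items)
        scores = rrb_subtype_scores(table, sets)
        assert scores.iloc[0].sum() == len(items)


class TestCorrelationAnalysis:
    def make_cohort(self, n=12, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        strength = rng.uniform(0, 1, n)
        return pd.DataFrame(
            {
                "subject": [f"s{i}" for i in range(n)],
                "group": ["HR-ASD"] * n,
                "conn": strength,
                "adi_rrb": 2.0 + 10.0 * strength + rng.normal(0, noise, n),
            }
        )

    def test_noise_free_monotone_trait_gives_rho_one(self):
        table = correlation_analysis(
            self.make_cohort(), ["HR-ASD"], {"global": "conn"}, ["adi_rrb"]
        )
        assert table["rho"].iloc[0] == pytest.approx(1.0)

    def test_fdr_family_columns_appended(self):
        table = correlation_analysis(
            self.make_cohort(noise=5.0), None, {"global": "conn"}, ["adi_rrb"], fdr_q=0.05
        )
        assert {"p_fdr", "significant_fdr"} <= set(table.columns)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="need >= 4"):
            correlation_analysis(
                self.make_cohort(n=3), None, {"global": "conn"}, ["adi_rrb"]
            )
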