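import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaboloss.multinomial_mwas import (
    SeparationError,
    SingularDesignError,
    augmented_term_test,
    bh_fdr,
    build_design,
    fit_multinomial,
    screen_metabolites,
    wald_test,
)


def _binary_cells():
    """x=1: 30 case / 70 ref; x=0: 10 case / 90 ref."""
    x = np.r_[np.ones(100), np.zeros(100)]
    y = np.r_[
        np.ones(30), np.zeros(70), np.ones(10), np.zeros(90)
    ].astype(int)
    X = np.column_stack([np.ones(200), x])
    return y, X


class TestClosedForms:
    def test_binary_logit_contingency_table(self):
        y, X = _binary_cells()
        fit = fit_multinomial(y, X, ["ref", "case"], ["(intercept)", "x"])
        assert fit.converged
        assert fit.coef_for("case", "x") == pytest.approx(
            np.log(30 * 90 / (70 * 10)), abs=1e-8
        )
        assert fit.coef_for("case", "(intercept)") == pytest.approx(
            np.log(10 / 90), abs=1e-8
        )

    def test_binary_wald_se_matches_woolf_variance(self):
        y, X = _binary_cells()
        fit = fit_multinomial(y, X, ["ref", "case"], ["(intercept)", "x"])
        assert fit.se_for("case", "x") == pytest.approx(
            np.sqrt(1 / 30 + 1 / 70 + 1 / 10 + 1 / 90), abs=1e-8
        )
        z, p = wald_test(fit, "x", "case")
        assert z == pytest.approx(1.349926716949016 / 0.3984095364447979,
                                  abs=1e-6)
        assert p == pytest.approx(7.03e-4, rel=0.01)

    def test_three_category_saturated_model(self):
        # x=1: ref 50 / A 25 / B 25; x=0: ref 80 / A 10 / B 10
        x = np.r_[np.ones(100), np.zeros(100)]
        y = np.r_[
            np.zeros(50), np.ones(25), 2 * np.ones(25),
            np.zeros(80), np.ones(10), 2 * np.ones(10),
        ].astype(int)
        X = np.column_stack([np.ones(200), x])
        fit = fit_multinomial(y, X, ["ref", "A", "B"], ["(intercept)", "x"])
        assert fit.coef_for("A", "x") == pytest.approx(np.log(4), abs=1e-8)
        assert fit.coef_for("B", "x") == pytest.approx(np.log(4), abs=1e-8)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_statsmodels_on_random_designs(self, seed):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(seed)
        n, p, K = 300, 3, 3
        X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
        B_true = rng.normal(0, 0.5, size=(K - 1, p))
        eta = np.concatenate([np.zeros((n, 1)), X @ B_true.T], axis=1)
        pr = np.exp(eta) / np.exp(eta).sum(axis=1, keepdims=True)
        y = (pr.cumsum(axis=1) < rng.random((n, 1))).sum(axis=1)
        fit = fit_multinomial(y, X)
        ref = sm.MNLogit(y, X).fit(disp=0, method="newton", tol=1e-12)
        assert np.allclose(fit.coef, ref.params.T, atol=1e-6)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-8)

    def test_collapse_to_binary_reproduces_closed_form(self):
        # merge both non-reference categories of the saturated 3-cat data
        x = np.r_[np.ones(100), np.zeros(100)]
        y3 = np.r_[
            np.zeros(50), np.ones(25), 2 * np.ones(25),
            np.zeros(80), np.ones(10), 2 * np.ones(10),
        ].astype(int)
        y2 = (y3 > 0).astype(int)
        X = np.column_stack([np.ones(200), x])
        fit = fit_multinomial(y2, X, ["ref", "any"], ["(intercept)", "x"])
        # collapsed cells: x=1 -> 50 case / 50 ref; x=0 -> 20 case / 80 ref
        assert fit.coef_for("any", "x") == pytest.approx(
            np.log((50 * 80) / (50 * 20)), abs=1e-8
        )


class TestFitProperties:
    def test_affine_equivariance(self):
        rng = np.random.default_rng(3)
        n = 400
        x = rng.standard_normal(n)
        eta = 0.8 * x
        pr = 1 / (1 + np.exp(-eta))
        y = (rng.random(n) < pr).astype(int)
        X1 = np.column_stack([np.ones(n), x])
        X2 = np.column_stack([np.ones(n), 10.0 * x])
        f1 = fit_multinomial(y, X1, ["a", "b"], ["(intercept)", "x"])
        f2 = fit_multinomial(y, X2, ["a", "b"], ["(intercept)", "x"])
        assert f2.coef_for("b", "x") == pytest.approx(
            f1.coef_for("b", "x") / 10.0, abs=1e-8
        )
        z1, _ = wald_test(f1, "x", "b")
        z2, _ = wald_test(f2, "x", "b")
        assert z1 == pytest.approx(z2, abs=1e-8)

    def test_loglik_nondecreasing_over_accepted_steps(self):
        y, X = _binary_cells()
        fit = fit_multinomial(y, X)
        diffs = np.diff(fit.ll_trace)
        assert (diffs >= -1e-9).all()

    def test_separation_raises_with_ridge_advice(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = x.astype(int)  # perfectly separated
        X = np.column_stack([np.ones(40), x])
        with pytest.raises(SeparationError):
            fit_multinomial(y, X)
        fit = fit_multinomial(y, X, ridge=1e-4)
        assert fit.ridge_used

    def test_singular_design_names_columns(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        X = np.column_stack([np.ones(50), x, 2 * x])
        y = (rng.random(50) < 0.5).astype(int)
        with pytest.raises(SingularDesignError, match="dup"):
            fit_multinomial(y, X, colnames=["(intercept)", "x", "dup"])

    def test_wald_identities(self):
        y, X = _binary_cells()
        fit = fit_multinomial(y, X, ["ref", "case"], ["(intercept)", "x"])
        fit.coef[0, 1] = 0.0
        _, p = wald_test(fit, "x", "case")
        assert p == pytest.approx(1.0)
        fit.coef[0, 1] = 1.959964 * fit.se_for("case", "x")
        _, p = wald_test(fit, "x", "case")
        assert p == pytest.approx(0.05, abs=1e-6)


def _bh_bruteforce(p, q):
    """Literal step-up definition, quadratic adjusted values."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    reject = np.zeros(m, bool)
    istar = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * q / m:
            istar = i
    reject[order[:istar]] = True
    adj = np.empty(m)
    for rank, idx in enumerate(order, start=1):
        adj[idx] = min(
            min(m * p[order[j - 1]] / j for j in range(rank, m + 1)), 1.0
        )
    return adj, reject


class TestBHFDR:
    @pytest.mark.parametrize(
        "pvals,expected_reject",
        [
            ([0.01, 0.02, 0.03, 0.04], [True] * 4),
            ([0.04, 0.5, 0.6], [False] * 3),
            ([0.05], [True]),  # single test at the boundary
        ],
    )
    def test_step_up_examples(self, pvals, expected_reject):
        _, reject = bh_fdr(pvals)
        assert reject.tolist() == expected_reject

    def test_adjusted_values_dominate_raw(self):
        rng = np.random.default_rng(2)
        p = rng.random(100)
        adj, _ = bh_fdr(p)
        assert (adj >= p - 1e-15).all()

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=200)
    def test_matches_bruteforce_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(1, 40))
        p = np.round(rng.random(m), 3)  # ties likely
        adj, reject = bh_fdr(p)
        adj_b, reject_b = _bh_bruteforce(p, 0.05)
        assert np.allclose(adj, adj_b, atol=1e-12)
        assert (reject == reject_b).all()

    def test_matches_statsmodels(self):
        mt = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(4)
        p = rng.random(200) ** 2
        adj, reject = bh_fdr(p)
        ref_rej, ref_adj, *_ = mt.multipletests(p, 0.05, method="fdr_bh")
        assert np.allclose(adj, ref_adj, atol=1e-12)
        assert (reject == ref_rej).all()

    def test_rejects_invalid_pvalues(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestScreen:
    def test_planted_effect_detected_with_correct_sign(self, demo_cohort):
        tab = screen_metabolites(
            demo_cohort["processed"], demo_cohort["cohort"],
            covariate_set="M_bmi",
        )
        row = tab[
            (tab["metabolite"] == "met_0000")
            & (tab["contrast"] == "unintentional_loss")
        ].iloc[0]
        assert row["beta"] > 0
        assert row["p"] < 0.05
        assert row["ci_low"] < row["or"] < row["ci_high"]

    def test_permuting_metabolite_destroys_association(self, demo_cohort):
        rng = np.random.default_rng(0)
        proc = demo_cohort["processed"][["met_0000"]].copy()
        proc["met_0000"] = rng.permutation(proc["met_0000"].to_numpy())
        tab = screen_metabolites(proc, demo_cohort["cohort"])
        p = tab[tab["contrast"] == "unintentional_loss"]["p"].iloc[0]
        assert p > 0.01  # no longer extreme

    def test_q_dominates_p_and_flags_consistent(self, demo_cohort):
        tab = screen_metabolites(
            demo_cohort["processed"], demo_cohort["cohort"]
        )
        assert (tab["q"] >= tab["p"] - 1e-15).all()
        assert (tab["sig_p05"] == (tab["p"] < 0.05)).all()
        assert (tab["sig_fdr05"] == (tab["q"] <= 0.05)).all()


class TestAugmentedTerms:
    def test_constant_modifier_is_an_error(self, demo_cohort):
        cohort = demo_cohort["cohort"].copy()
        cohort["sex"] = "men"
        with pytest.raises(ValueError, match="constant"):
            augmented_term_test(
                demo_cohort["processed"], cohort, "met_0000",
                kind="interaction", modifier="sex",
            )

    def test_square_term_null_for_linear_effect(self, demo_cohort):
        p = augmented_term_test(
            demo_cohort["processed"], demo_cohort["cohort"], "met_0000",
            kind="square",
        )
        assert 0.0 <= p <= 1.0

    def test_bmi_interaction_uses_joint_chi_square(self, demo_cohort):
        p = augmented_term_test(
            demo_cohort["processed"], demo_cohort["cohort"], "met_0000",
            kind="interaction", modifier="bmi_cat",
        )
        assert 0.0 <= p <= 1.0


class TestBuildDesign:
    def test_categorical_expansion_against_reference(self):
        df = pd.DataFrame(
            {"age": [70.0, 75.0], "sex": ["men", "women"],
             "bmi_cat": ["<25", ">=30"]}
        )
        X = build_design(df, ["age", "sex", "bmi_cat"])
        assert list(X.columns) == [
            "(intercept)", "age", "sex[women]", "bmi_cat[>=30]",
        ]
        assert X["sex[women]"].tolist() == [0.0, 1.0]
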