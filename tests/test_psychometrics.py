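"""Measurement layer: z-scoring, one-factor extraction, omega, composites."""

import numpy as np
import pandas as pd
import pytest

from traitsynergy import (FactorSolution, SingleFactorModel, coefficient_omega,
                          factor_scores, fit_single_factor, keyed_item_matrix,
                          load_item_specs, score_composite, standardize)
from traitsynergy.psychometrics import EPSILON_FLOOR, ItemSpec
from traitsynergy.simulate import generate_population, make_config

TEST_COLS = [f"test_{j}" for j in range(1, 13)]


class TestStandardize:
    def test_three_point_example(self):
        np.testing.assert_allclose(standardize([1, 2, 3]), [-1, 0, 1], atol=1e-12)

    def test_sample_sd_denominator(self):
        # mean 30, sample sd sqrt(1000/3) = 18.2574
        z = standardize([10.0, 20.0, 40.0, 50.0])
        np.testing.assert_allclose(z, [-1.09545, -0.54772, 0.54772, 1.09545], atol=1e-5)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        z = standardize(rng.normal(5, 3, 100))
        np.testing.assert_allclose(standardize(z), z, atol=1e-12)

    def test_missing_preserved(self):
        z = standardize(pd.Series([1.0, np.nan, 3.0, 5.0]))
        assert np.isnan(z[1]) and np.isfinite(z[[0, 2, 3]]).all()

    @pytest.mark.parametrize("bad", [[2.0, 2.0, 2.0], [1.0], [np.nan, np.nan]])
    def test_degenerate_input_rejected(self, bad):
        with pytest.raises(ValueError):
            standardize(bad)


class TestSingleFactorModel:
    def test_closed_form_three_indicators(self):
        # population r_ij = 0.49 for all pairs -> lambda_i = 0.7 exactly
        R = np.full((3, 3), 0.49)
        np.fill_diagonal(R, 1.0)
        sol = SingleFactorModel.from_correlation(R)
        assert sol.converged
        np.testing.assert_allclose(sol.loadings, 0.7, atol=1e-6)
        np.testing.assert_allclose(sol.uniquenesses, 0.51, atol=1e-6)

    def test_recovers_equal_loadings(self, rg_sim):
        # ability battery generated with true loadings 0.7
        model = rg_sim["model"]
        assert model.converged_ and model.method_used_ == "ml"
        np.testing.assert_allclose(model.loadings_, 0.7, atol=0.01)
        assert np.all(model.loadings_**2 + model.uniquenesses_ - 1 < 0.02)

    def test_rank_one_limit_hits_uniqueness_floor(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal(400)
        X = np.column_stack([base + 1e-6 * rng.standard_normal(400) for _ in range(3)])
        sol = fit_single_factor(X)
        np.testing.assert_allclose(np.abs(sol.loadings), 1.0, atol=0.01)
        assert np.all(sol.uniquenesses <= EPSILON_FLOOR + 1e-6)

    def test_matches_statsmodels_ml_factor(self):
        sm_factor = pytest.importorskip("statsmodels.multivariate.factor")
        rng = np.random.default_rng(5)
        f = rng.standard_normal(5000)
        lam = np.array([0.8, 0.7, 0.6, 0.5, 0.4, 0.65])
        X = lam * f[:, None] + np.sqrt(1 - lam**2) * rng.standard_normal((5000, 6))
        ours = fit_single_factor(X)
        theirs = sm_factor.Factor(X, n_factor=1, method="ml").fit()
        ref = np.abs(theirs.loadings.ravel())
        np.testing.assert_allclose(np.abs(ours.loadings), ref, atol=5e-3)

    def test_too_few_indicators_rejected(self):
        with pytest.raises(ValueError):
            SingleFactorModel().fit(np.random.default_rng(0).normal(size=(50, 2)))

    def test_sklearn_param_interface(self):
        m = SingleFactorModel()
        assert m.get_params()["method"] == "ml"
        m.set_params(method="minres")
        assert m.method == "minres"
        with pytest.raises(ValueError):
            m.set_params(bogus=1)


class TestFactorScores:
    def test_perfect_single_indicator_returns_standardized_indicator(self):
        sol = FactorSolution(
            loadings=np.array([1.0]), uniquenesses=np.array([EPSILON_FLOOR]),
            indicator_names=["x1"], method="ml", converged=True,
        )
        rng = np.random.default_rng(2)
        x = rng.normal(10, 2, size=(200, 1))
        scores = factor_scores(sol, x, min_present=1)
        np.testing.assert_allclose(scores, standardize(x[:, 0]), atol=1e-10)

    def test_score_determinacy_against_truth(self, rg_sim):
        iq = rg_sim["iq"]
        r = np.corrcoef(iq, rg_sim["truth"]["g"])[0, 1]
        assert r >= 0.95

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        f = rng.standard_normal(300)
        X = 0.7 * f[:, None] + 0.5 * rng.standard_normal((300, 4))
        model = SingleFactorModel().fit(X)
        scores = model.transform(X)
        perm = rng.permutation(300)
        np.testing.assert_allclose(model.transform(X[perm]), scores[perm], atol=1e-10)

    def test_missing_indicator_rule(self, rg_sim):
        X = rg_sim["data"][TEST_COLS].head(500).to_numpy().copy()
        X[0, :5] = np.nan   # 7 of 12 present -> below the 8-indicator minimum
        X[1, :4] = np.nan   # 8 of 12 present -> scored
        X[2, :] = np.nan    # nothing present -> missing
        scores = factor_scores(rg_sim["model"].solution_(), X)
        assert np.isnan(scores[0]) and np.isnan(scores[2])
        assert np.isfinite(scores[1])


class TestCoefficientOmega:
    def test_error_free_items_have_unit_omega(self):
        sol = FactorSolution(np.full(4, 0.8), np.zeros(4), list("abcd"), "ml", True)
        assert coefficient_omega(sol) == pytest.approx(1.0)

    def test_formula_value(self):
        sol = FactorSolution(np.full(5, 0.6), np.full(5, 0.64), list("abcde"), "ml", True)
        assert coefficient_omega(sol) == pytest.approx(9.0 / 12.2, abs=1e-12)

    def test_equals_alpha_under_tau_equivalence(self):
        # independent variance-ratio oracle for Cronbach's alpha
        rng = np.random.default_rng(4)
        f = rng.standard_normal(20_000)
        K = 6
        X = 0.6 * f[:, None] + 0.8 * rng.standard_normal((20_000, K))
        sol = fit_single_factor(X)
        S = np.cov(X, rowvar=False)
        alpha = K / (K - 1) * (1 - np.trace(S) / S.sum())
        assert coefficient_omega(sol) == pytest.approx(alpha, abs=0.005)

    def test_invariant_to_consistent_reverse_keying(self):
        # storing items reversed and flagging them reversed must not move omega
        rng = np.random.default_rng(6)
        f = rng.standard_normal(5000)
        X = 0.6 * f[:, None] + 0.7 * rng.standard_normal((5000, 5))
        specs_fwd = [ItemSpec(j + 1, f"i{j}", 1, 5, False, "dependable") for j in range(5)]
        specs_rev = [ItemSpec(j + 1, f"i{j}", 1, 5, j in (1, 3), "dependable") for j in range(5)]
        data_fwd = pd.DataFrame(X, columns=[f"item_{j + 1}" for j in range(5)])
        data_rev = data_fwd.copy()
        for j in (1, 3):
            data_rev[f"item_{j + 1}"] *= -1
        om_a = coefficient_omega(fit_single_factor(keyed_item_matrix(data_fwd, specs_fwd, "dependable")))
        om_b = coefficient_omega(fit_single_factor(keyed_item_matrix(data_rev, specs_rev, "dependable")))
        assert om_a == pytest.approx(om_b, abs=1e-8)

    def test_split_half_stability(self, rg_sim, specs):
        items = keyed_item_matrix(rg_sim["data"], specs, "dependable").to_numpy()
        half = len(items) // 2
        om1 = coefficient_omega(fit_single_factor(items[:half]))
        om2 = coefficient_omega(fit_single_factor(items[half:]))
        assert abs(om1 - om2) < 0.02


def _one_item_spec(reverse):
    return [ItemSpec(1, "solo", 1, 5, reverse, "dependable")]


class TestScoreComposite:
    def test_single_item_composite_is_standardized_item(self):
        rng = np.random.default_rng(7)
        data = pd.DataFrame({"item_1": rng.integers(1, 6, 300).astype(float)})
        comp = score_composite(data, _one_item_spec(False), "dependable")
        np.testing.assert_allclose(comp, standardize(data["item_1"]), atol=1e-12)

    def test_single_reversed_item_is_negated(self):
        rng = np.random.default_rng(8)
        data = pd.DataFrame({"item_1": rng.integers(1, 6, 300).astype(float)})
        comp = score_composite(data, _one_item_spec(True), "dependable")
        np.testing.assert_allclose(comp, -standardize(data["item_1"]), atol=1e-12)

    def test_all_member_items_missing_gives_missing(self, specs):
        cfg = make_config("null", {"n": 50, "seed": 11})
        data, _ = generate_population(cfg)
        dep_cols = [s.column for s in specs if s.composite == "dependable"]
        data.loc[0, dep_cols] = np.nan
        comp = score_composite(data, specs, "dependable")
        assert np.isnan(comp.iloc[0]) and comp.iloc[1:].notna().all()

    def test_composite_validity_matches_spearman_oracle(self, specs):
        # continuous items, equal loadings: corr(composite, T) = sqrt(K r / (1 + (K-1) r))
        cfg = make_config(
            "custom",
            {"n": 100_000, "seed": 12, "likert": False,
             "item_loadings": (0.6,) * 18, "error_base_sd": 1.0},
        )
        data, truth = generate_population(cfg)
        comp = score_composite(data, specs, "dependable")
        K = 5
        r_item = 0.36 / 1.36
        expected = np.sqrt(K * r_item / (1 + (K - 1) * r_item))
        observed = np.corrcoef(comp, truth["T"])[0, 1]
        assert observed == pytest.approx(expected, abs=0.02)

    def test_item_two_excluded_from_final_dependable(self, specs):
        dep = [s.item for s in specs if s.composite == "dependable"]
        assert sorted(dep) == [1, 3, 4, 11, 16]
        with_excluded = load_item_specs(include_excluded=True)
        dep6 = [s.item for s in with_excluded if s.composite == "dependable"]
        assert sorted(dep6) == [1, 2, 3, 4, 11, 16]
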