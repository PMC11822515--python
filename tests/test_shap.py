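from itertools import combinations
from math import comb, factorial

import numpy as np
import pandas as pd
import pytest

from wormqsar.data import DescriptorMatrix
from wormqsar.gbt import Hyperparameters, fit_gbt
from wormqsar.shap_kernel import (Explanation, explain, importance_ranking,
                                  impute_coalition, shap_kernel_weight)


def exact_shapley(value_fn, M):
    """Independent oracle: Shapley values by full subset enumeration."""
    phi = np.zeros(M)
    for i in range(M):
        others = [j for j in range(M) if j != i]
        for r in range(M):
            for S in combinations(others, r):
                w = factorial(len(S)) * factorial(M - len(S) - 1) / factorial(M)
                phi[i] += w * (value_fn(set(S) | {i}) - value_fn(set(S)))
    return phi


def _tree_model_and_background(M, seed, n=80):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, M)), columns=[f"d{i}" for i in range(M)])
    X.index = pd.Index([f"c{i}" for i in range(n)], name="compound_id")
    y = (X.iloc[:, 0] + 0.7 * X.iloc[:, 1 % M] * X.iloc[:, 2 % M]
         + rng.normal(0, 0.4, n) > 0).astype(int)
    model = fit_gbt(DescriptorMatrix(X, pd.Series(y, index=X.index)),
                    Hyperparameters(n_trees=60, max_depth=3, feature_fraction=0.8,
                                    row_fraction=0.9), seed=seed)
    background = DescriptorMatrix(X.iloc[[int(rng.integers(n))]])
    x = X.iloc[int(rng.integers(n))].to_numpy()
    return model, background, x


class TestKernelWeight:
    @pytest.mark.parametrize("M,s,expected", [
        (4, 1, 3 / (4 * 1 * 3)),
        (4, 2, 3 / (6 * 2 * 2)),
        (6, 1, 5 / (6 * 1 * 5)),
    ])
    def test_closed_form(self, M, s, expected):
        assert shap_kernel_weight(M, s) == pytest.approx(expected)

    def test_symmetry_in_coalition_size(self):
        for M in range(3, 10):
            for s in range(1, M):
                assert shap_kernel_weight(M, s) == pytest.approx(
                    shap_kernel_weight(M, M - s))

    def test_singleton_coalitions_carry_most_weight(self):
        M = 8
        weights = [shap_kernel_weight(M, s) for s in range(1, M)]
        assert max(weights) == weights[0] == weights[-1]

    @pytest.mark.parametrize("s", [0, 4])
    def test_trivial_coalitions_are_constraints(self, s):
        with pytest.raises(ValueError, match="constraints"):
            shap_kernel_weight(4, s)


class TestImputeCoalition:
    def test_complete_coalition_returns_x(self):
        bg = DescriptorMatrix(pd.DataFrame(np.zeros((3, 4)), columns=list("abcd")))
        x = np.arange(4.0)
        out = impute_coalition(x, np.ones(4, dtype=bool), bg, seed=0)
        assert np.array_equal(out, x)

    def test_empty_coalition_returns_background_row(self):
        rows = np.arange(12.0).reshape(3, 4)
        bg = DescriptorMatrix(pd.DataFrame(rows, columns=list("abcd")))
        out = impute_coalition(np.full(4, -1.0), np.zeros(4, dtype=bool), bg, seed=5)
        assert any(np.array_equal(out, r) for r in rows)

    def test_single_row_background_is_deterministic(self):
        bg = DescriptorMatrix(pd.DataFrame([[9.0, 8.0, 7.0]], columns=list("abc")))
        x = np.array([1.0, 2.0, 3.0])
        z = np.array([True, False, True])
        for seed in range(5):
            assert np.array_equal(impute_coalition(x, z, bg, seed), [1.0, 8.0, 3.0])

    def test_empty_background_rejected(self):
        bg = DescriptorMatrix(pd.DataFrame(columns=list("ab"), dtype=float))
        with pytest.raises(ValueError, match="nonempty"):
            impute_coalition(np.zeros(2), np.zeros(2, dtype=bool), bg, seed=0)


class TestExplain:
    @pytest.mark.parametrize("M", [3, 5, 8])
    def test_matches_exact_shapley_with_deterministic_imputation(self, M):
        model, background, x = _tree_model_and_background(M, seed=M)
        bg_row = background.X.iloc[0].to_numpy()

        def value(S):
            z = bg_row.copy()
            idx = sorted(S)
            z[idx] = x[idx]
            return float(model.predict_proba_array(z[None, :])[0])

        oracle = exact_shapley(value, M)
        result = explain(model, x, background, n_imputation_replicates=1, seed=0)
        np.testing.assert_allclose(result.betas.to_numpy(), oracle, atol=1e-6)

    def test_efficiency_identity_holds_exactly(self):
        model, background, x = _tree_model_and_background(6, seed=2)
        result = explain(model, x, background, n_imputation_replicates=4, seed=1)
        fx = float(model.predict_proba_array(x[None, :])[0])
        assert result.beta0 + result.betas.sum() == pytest.approx(fx, abs=1e-10)

    def test_additive_model_recovers_marginal_contributions(self):
        # For f additive in independent inputs, beta_i -> x_i - E[bg_i].
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(400, 2)), columns=["a", "b"])
        X.index = pd.Index([f"c{i}" for i in range(400)], name="compound_id")

        class AdditiveModel:
            descriptor_names = ["a", "b"]

            def predict_proba_array(self, rows):
                rows = np.atleast_2d(rows)
                return 0.25 * rows[:, 0] + 0.15 * rows[:, 1] + 0.5

        x = np.array([1.0, -2.0])
        bg = DescriptorMatrix(X)
        result = explain(AdditiveModel(), x, bg, n_imputation_replicates=200, seed=0)
        assert result.betas["a"] == pytest.approx(0.25 * (1.0 - X["a"].mean()), abs=0.02)
        assert result.betas["b"] == pytest.approx(0.15 * (-2.0 - X["b"].mean()), abs=0.02)

    def test_symmetric_duplicate_descriptors_get_equal_attributions(self):
        class SumModel:
            descriptor_names = ["a", "b", "c"]

            def predict_proba_array(self, rows):
                rows = np.atleast_2d(rows)
                return 0.2 * (rows[:, 0] + rows[:, 1]) + 0.1 * rows[:, 2]

        bg = DescriptorMatrix(pd.DataFrame([[0.0, 0.0, 0.0]], columns=list("abc")))
        result = explain(SumModel(), np.array([1.0, 1.0, 1.0]), bg,
                         n_imputation_replicates=1, seed=0)
        assert result.betas["a"] == pytest.approx(result.betas["b"], abs=1e-9)

    def test_dummy_descriptor_gets_zero_attribution(self):
        # Model ignores its last input entirely.
        class PartialModel:
            descriptor_names = ["a", "b", "dummy"]

            def predict_proba_array(self, rows):
                rows = np.atleast_2d(rows)
                return 1 / (1 + np.exp(-(rows[:, 0] - rows[:, 1])))

        bg = DescriptorMatrix(pd.DataFrame([[0.5, -0.5, 3.0]], columns=["a", "b", "dummy"]))
        result = explain(PartialModel(), np.array([2.0, 1.0, -3.0]), bg,
                         n_imputation_replicates=1, seed=0)
        assert result.betas["dummy"] == pytest.approx(0.0, abs=1e-9)

    def test_coalition_sampler_draws_valid_nontrivial_coalitions(self):
        from wormqsar.shap_kernel import _coalition_matrix

        rng = np.random.default_rng(1)
        Z = _coalition_matrix(20, rng, budget=500)  # 2^20 forces the sampler
        assert Z.shape == (500, 20)
        sizes = set(map(int, Z.sum(axis=1)))
        assert sizes <= set(range(1, 20))
        assert 1 in sizes or 19 in sizes  # kernel mass concentrates at the ends


class TestImportanceRanking:
    def _explanation(self, cid, values):
        return Explanation(cid, 0.0, pd.Series(values))

    def test_single_explanation_orders_by_abs_value(self):
        table = importance_ranking([self._explanation("c1", {"a": -0.5, "b": 0.2})])
        assert list(table["descriptor"]) == ["a", "b"]
        assert list(table["rank"]) == [1, 2]

    def test_zero_descriptor_ranked_last_and_ties_alphabetical(self):
        exps = [self._explanation("c1", {"x": 0.3, "b": 0.3, "z": 0.0})]
        table = importance_ranking(exps)
        assert list(table["descriptor"]) == ["b", "x", "z"]

    def test_mean_abs_aggregation_over_compounds(self):
        exps = [self._explanation("c1", {"a": 1.0, "b": 0.0}),
                self._explanation("c2", {"a": -1.0, "b": 0.1})]
        table = importance_ranking(exps)
        assert table.loc[table["descriptor"] == "a", "mean_abs_shap"].item() == 1.0
        assert list(table["descriptor"]) == ["a", "b"]

    def test_requires_at_least_one_explanation(self):
        with pytest.raises(ValueError):
            importance_ranking([])

    def test_planted_signal_descriptor_ranks_first(self):
        model, background, _ = _tree_model_and_background(4, seed=7, n=150)
        rng = np.random.default_rng(0)
        exps = []
        for i in range(10):
            x = rng.normal(size=4)
            exps.append(explain(model, x, background, n_imputation_replicates=1,
                                seed=i, compound_id=f"q{i}"))
        table = importance_ranking(exps)
        assert table.iloc[0]["descriptor"] in ("d0", "d1", "d2")
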