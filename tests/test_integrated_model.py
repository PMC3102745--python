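"""The logistic model: design matrix contracts, IRLS correctness, stepwise
selection, ROC/cross-validation machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from tfbsc import integrated_model as im


def _logistic(eta):
    return 1 / (1 + np.exp(-eta))


class TestDesignMatrix:
    def test_polynomial_columns_mutually_orthogonal_and_centered(self):
        rng = np.random.default_rng(0)
        P = im.orthogonal_poly(rng.uniform(0, 1000, 500), 3)
        G = P.T @ P
        assert np.all(np.abs(G - np.diag(np.diag(G))) < 1e-8)
        assert np.all(np.abs(P.mean(axis=0)) < 1e-10)   # orthogonal to intercept
        assert np.allclose(P.std(axis=0), 1.0)

    def test_hierarchy_contrast_values(self):
        C = im.hierarchy_contrasts(["top", "core", "bottom"])
        assert C[:, 0] == pytest.approx([1 / np.sqrt(2), 0, -1 / np.sqrt(2)])
        assert C[:, 1] == pytest.approx(
            [1 / np.sqrt(6), -2 / np.sqrt(6), 1 / np.sqrt(6)]
        )

    def test_predictions_invariant_to_distance_basis(self):
        rng = np.random.default_rng(1)
        d = rng.uniform(0, 1000, 800)
        y = (rng.random(800) < _logistic(1 - 0.003 * d)).astype(float)
        X_orth = np.column_stack([np.ones(800), im.orthogonal_poly(d, 3)])
        dc = d - d.mean()
        X_raw = np.column_stack([np.ones(800), dc / 100,
                                 (dc / 100) ** 2, (dc / 100) ** 3])
        mu_orth = im.fit_binomial_glm(X_orth, y).mu
        mu_raw = im.fit_binomial_glm(X_raw, y).mu
        assert np.allclose(mu_orth, mu_raw, atol=1e-7)

    def test_unassigned_hierarchy_rows_excluded(self):
        df = pd.DataFrame(
            {"tf_hierarchy": ["top", "unassigned", "bottom", "core"],
             "strength": [0.7, 0.8, 0.9, 1.0]}
        )
        X, tm = im.build_design_matrix(df, ["strength", "hierarchy"])
        assert len(X) == 3
        assert "hierarchy" in tm

    def test_constant_term_dropped_with_warning(self, caplog):
        df = pd.DataFrame({"subtelomeric": [False] * 10,
                           "strength": np.linspace(0.6, 1, 10)})
        with caplog.at_level("WARNING", logger="tfbsc"):
            _X, tm = im.build_design_matrix(df, ["strength", "subtelomeric"])
        assert "subtelomeric" not in tm


class TestGLMFit:
    def test_saturated_two_group_closed_form(self):
        # group A: 20/30 conserved, group B: 10/30
        x = np.repeat([1.0, 0.0], 30)
        y = np.concatenate([np.ones(20), np.zeros(10), np.ones(10), np.zeros(20)])
        fit = im.fit_binomial_glm(np.column_stack([np.ones(60), x]), y)
        assert fit.beta[0] == pytest.approx(np.log(0.5), abs=1e-8)
        assert fit.beta[1] == pytest.approx(np.log(4.0), abs=1e-8)

    def test_all_one_outcome_is_separation(self):
        X = np.column_stack([np.ones(20), np.arange(20.0)])
        with pytest.raises(im.SeparationError):
            im.fit_binomial_glm(X, np.ones(20))

    def test_perfectly_separated_predictor_is_detected(self):
        x = np.repeat([0.0, 1.0], 25)
        with pytest.raises(im.SeparationError):
            im.fit_binomial_glm(np.column_stack([np.ones(50), x]), x)

    def test_matches_generic_optimizer_on_five_covariates(self):
        rng = np.random.default_rng(2)
        n = 2000
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 5))])
        beta_true = np.array([-0.4, 0.8, -0.6, 0.3, 0.0, 1.1])
        y = (rng.random(n) < _logistic(X @ beta_true)).astype(float)
        fit = im.fit_binomial_glm(X, y)

        def nll(b):
            eta = X @ b
            return np.logaddexp(0, eta).sum() - y @ eta

        res = optimize.minimize(nll, np.zeros(6), method="BFGS",
                                options={"gtol": 1e-10})
        assert np.allclose(fit.beta, res.x, atol=1e-6)

    def test_deviance_weakly_decreases_with_added_term(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(300), rng.normal(size=(300, 2))])
        y = (rng.random(300) < 0.4).astype(float)
        full = im.fit_binomial_glm(X, y)
        reduced = im.fit_binomial_glm(X[:, :2], y)
        assert full.deviance <= reduced.deviance + 1e-10


class TestDevianceCompare:
    def test_identical_models(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame({"intercept": np.ones(100),
                          "x": rng.normal(size=100)})
        y = (rng.random(100) < 0.5).astype(float)
        fit = im.fit_binomial_glm(X, y)
        chi2, df, p = im.deviance_compare(fit, fit)
        assert (chi2, df, p) == (0.0, 0, 1.0)

    def test_non_nested_models_rejected(self):
        rng = np.random.default_rng(5)
        Xa = pd.DataFrame({"intercept": np.ones(100), "a": rng.normal(size=100)})
        Xb = pd.DataFrame({"intercept": np.ones(100), "b": rng.normal(size=100)})
        y = (rng.random(100) < 0.5).astype(float)
        with pytest.raises(ValueError, match="nested"):
            im.deviance_compare(im.fit_binomial_glm(Xa, y),
                                im.fit_binomial_glm(Xb, y))


def _interaction_data(rng, n, beta_int=0.0):
    x1 = rng.normal(size=n)
    x2 = (rng.random(n) < 0.4).astype(float)
    x3 = rng.normal(size=n)
    eta = 0.3 + 0.8 * x1 + 0.6 * x2 - 0.5 * x3 + beta_int * x1 * x2
    y = (rng.random(n) < _logistic(eta)).astype(int)
    X = pd.DataFrame({"intercept": 1.0, "x1": x1, "x2": x2, "x3": x3})
    tm = {"x1": ["x1"], "x2": ["x2"], "x3": ["x3"]}
    Xi, full = im.add_interactions(X, tm)
    return Xi, full, y


class TestStepwise:
    def test_marginality_keeps_parents_of_retained_interactions(self):
        rng = np.random.default_rng(6)
        # strong interaction, weak mains: mains must survive regardless
        n = 4000
        x1 = rng.normal(size=n)
        x2 = (rng.random(n) < 0.5).astype(float)
        y = (rng.random(n) < _logistic(1.5 * x1 * x2)).astype(int)
        X = pd.DataFrame({"intercept": 1.0, "x1": x1, "x2": x2})
        Xi, full = im.add_interactions(X, {"x1": ["x1"], "x2": ["x2"]})
        fit, _log = im.stepwise_reduce(Xi, y, full)
        assert "x1:x2" in fit.terms
        assert {"x1", "x2"} <= set(fit.terms)

    def test_null_interactions_eliminated(self):
        rng = np.random.default_rng(7)
        Xi, full, y = _interaction_data(rng, 8000, beta_int=0.0)
        fit, log = im.stepwise_reduce(Xi, y, full)
        assert {"x1", "x2", "x3"} <= set(fit.terms)
        assert set(log["dropped"]).issubset({"x1:x2", "x1:x3", "x2:x3"})

    def test_elimination_log_records_p_values(self):
        rng = np.random.default_rng(8)
        Xi, full, y = _interaction_data(rng, 3000)
        _fit, log = im.stepwise_reduce(Xi, y, full)
        assert (log["p"] >= 0.05).all()
        assert list(log["step"]) == sorted(log["step"])


def _brute_force_auc(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n_) + 0.5 * (p == n_) for p in pos for n_ in neg)
    return wins / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation_gives_one(self):
        auc, _ = im.roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_pair_counting_example(self):
        auc, _ = im.roc_auc([0.9, 0.4, 0.8, 0.2], [1, 1, 0, 0])
        assert auc == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        auc, _ = im.roc_auc([0.5] * 10, [1, 0] * 5)
        assert auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            im.roc_auc([0.1, 0.9], [1, 1])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = np.round(rng.random(n), 2)  # ties likely
        auc, _ = im.roc_auc(scores, labels)
        assert auc == pytest.approx(_brute_force_auc(scores, labels), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        scores = rng.random(100)
        labels = rng.integers(0, 2, 100)
        a1, _ = im.roc_auc(scores, labels)
        a2, _ = im.roc_auc(np.exp(3 * scores), labels)
        assert a1 == pytest.approx(a2)


class TestCrossValidation:
    def _data(self, rng, n=1500):
        X = pd.DataFrame({"intercept": 1.0, "x": rng.normal(size=n)})
        y = (rng.random(n) < _logistic(1.2 * X["x"])).astype(int)
        return X, y.to_numpy()

    def test_same_seed_reproduces_folds_and_aucs(self):
        X, y = self._data(np.random.default_rng(10))
        a = im.cross_validated_auc(X, y, k=10, seed=3)
        b = im.cross_validated_auc(X, y, k=10, seed=3)
        assert np.array_equal(a.fold_aucs, b.fold_aucs)

    def test_shuffled_labels_give_chance_auc(self):
        rng = np.random.default_rng(11)
        X, y = self._data(rng)
        y_shuf = rng.permutation(y)
        cv = im.cross_validated_auc(X, y_shuf, k=10, seed=0)
        assert abs(cv.mean_auc - 0.5) < max(3 * cv.se_auc, 0.05)

    def test_se_is_fold_sd_over_sqrt_k(self):
        X, y = self._data(np.random.default_rng(12))
        cv = im.cross_validated_auc(X, y, k=10, seed=1)
        assert cv.se_auc == pytest.approx(cv.fold_aucs.std(ddof=1) / np.sqrt(10))


class TestSingleFeatureAndPerTf:
    def test_strength_is_top_single_feature_on_planted_data(self, small_sim):
        feats = small_sim.truth.reset_index(drop=True)
        y = feats["between_true"].to_numpy()
        table = im.single_feature_aucs(feats, y, terms=["strength", "n_tfs",
                                                        "subtelomeric"],
                                       k=5, seed=0)
        assert table.iloc[0]["feature"] == "strength"

    def test_per_tf_distribution_near_global(self, small_sim):
        feats = small_sim.truth.reset_index(drop=True)
        y = feats["between_true"].to_numpy()
        X, _ = im.build_design_matrix(feats)
        table, summary = im.per_tf_auc(X, y, feats["tf_id"].to_numpy(), min_n=20)
        global_auc, _ = im.roc_auc(im.fit_binomial_glm(X, y).mu, y)
        assert abs(summary["median_auc"] - global_auc) < 0.1
        assert summary["n_tfs"] >= 3


class TestValidatedShift:
    def test_whole_set_has_zero_shift(self):
        rng = np.random.default_rng(13)
        scores = pd.Series(rng.random(100),
                           index=[f"s{i}" for i in range(100)])
        res = im.validated_site_shift(scores, list(scores.index))
        assert res["median_shift"] == 0.0

    def test_top_decile_subset_shifts_high(self):
        rng = np.random.default_rng(14)
        scores = pd.Series(rng.random(500),
                           index=[f"s{i}" for i in range(500)])
        top = list(scores.sort_values(ascending=False).index[:20])
        res = im.validated_site_shift(scores, top)
        assert res["p_value"] < 0.01
        assert res["median_shift"] > 0

    def test_small_subset_rejected(self):
        scores = pd.Series([0.1, 0.2, 0.3], index=["a", "b", "c"])
        with pytest.raises(ValueError):
            im.validated_site_shift(scores, ["a", "b"])
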