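"""ICC, collinearity pruning, LASSO signatures, stepwise AIC, five models."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from habitatpipe.modeling import (
    Signature,
    clinical_design,
    fit_five_models,
    fit_l1_at_lambda,
    filter_stability,
    icc_2way_random_absolute,
    lasso_logistic_cv,
    pearson_prune,
    radscore,
    radscore_table,
    stepwise_aic_logistic,
    _fit_logit,
)


def _icc_anova_oracle(x):
    """From-scratch two-way ANOVA mean squares -> ICC(2,1)."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.mean()
    msr = k * sum((x[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = n * sum((x[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum(
        (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_perfect_agreement(self):
        x = np.column_stack([np.arange(6.0), np.arange(6.0)])
        assert icc_2way_random_absolute(x) == pytest.approx(1.0)

    def test_permuted_rater_destroys_agreement(self):
        r1 = np.array([1.0, 5.0, 9.0, 13.0, 17.0, 21.0])
        x = np.column_stack([r1, r1[::-1]])
        assert icc_2way_random_absolute(x) < 0.1

    def test_matches_anova_oracle_on_toy_table(self):
        x = np.array([[9, 2], [1, 10], [8, 8], [2, 6], [7, 8], [2, 4]], float)
        assert icc_2way_random_absolute(x) == pytest.approx(_icc_anova_oracle(x), abs=1e-9)

    def test_matches_pingouin_icc2(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(0)
        truth = rng.normal(size=12)
        x = np.column_stack([truth + rng.normal(0, 0.3, 12), truth + rng.normal(0, 0.3, 12)])
        long = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(12), 2),
                "raters": np.tile([0, 1], 12),
                "ratings": x.ravel(),
            }
        )
        ref = pg.intraclass_corr(long, targets="targets", raters="raters", ratings="ratings")
        icc2 = ref.loc[ref["Type"].isin(["ICC2", "ICC(A,1)"]), "ICC"].iloc[0]
        assert icc_2way_random_absolute(x) == pytest.approx(icc2, abs=1e-9)

    def test_zero_variance_defined_as_one(self):
        with pytest.warns(UserWarning):
            assert icc_2way_random_absolute(np.ones((5, 2))) == 1.0

    def test_stability_filter_boundary(self):
        icc = pd.Series({"a": 1.0, "b": 0.75, "c": 0.74, "d": 0.2})
        assert filter_stability(list("abcd"), icc) == ["a", "b"]
        assert filter_stability(["x"], pd.Series({"x": 0.2, "y": 0.76, "z": 0.74})) == []


class TestPearsonPrune:
    def test_identical_features_drop_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        df = pd.DataFrame({"a": x, "b": x})
        assert len(pearson_prune(df)) == 1

    def test_independent_features_all_kept(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(500, 6)), columns=list("abcdef"))
        assert sorted(pearson_prune(df)) == list("abcdef")

    def test_hub_feature_dropped_first(self):
        # r(1,2) ~ r(1,3) ~ 0.95, r(2,3) ~ 0.805 (anti-correlated noise keeps
        # the pair below threshold): the hub f1 has the largest mean |r|.
        rng = np.random.default_rng(3)
        n = 4000
        z = rng.normal(size=n)
        e = rng.normal(size=n)
        a, b = 0.95, np.sqrt(1 - 0.95**2)
        df = pd.DataFrame({"f1": z, "f2": a * z + b * e, "f3": a * z - b * e})
        c = df.corr().abs()
        assert c.loc["f1", "f2"] > 0.9 and c.loc["f1", "f3"] > 0.9 and c.loc["f2", "f3"] < 0.9
        kept = pearson_prune(df)
        assert "f1" not in kept and set(kept) == {"f2", "f3"}

    def test_constant_feature_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"a": rng.normal(size=50), "c": np.ones(50)})
        with pytest.warns(UserWarning, match="constant"):
            kept = pearson_prune(df)
        assert kept == ["a"]


def _newton_logistic(X, y, tol=1e-12, iters=200):
    """Unpenalized MLE by straight Newton-Raphson (test oracle)."""
    Xd = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(Xd.shape[1])
    for _ in range(iters):
        p = expit(Xd @ beta)
        grad = Xd.T @ (y - p)
        W = p * (1 - p)
        hess = (Xd * W[:, None]).T @ Xd
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


class TestLasso:
    def test_full_shrinkage_limit(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(100, 4))
        y = (rng.random(100) < 0.3).astype(int)
        w, b, _ = fit_l1_at_lambda(X, y, lam=10.0)
        assert np.all(w == 0)
        assert b == pytest.approx(logit(y.mean()), abs=0.05)

    def test_lambda_zero_matches_newton_oracle(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(200, 2))
        lp = 0.8 * X[:, 0] - 1.2 * X[:, 1]
        y = (rng.random(200) < expit(lp)).astype(int)
        w, b, _ = fit_l1_at_lambda(X, y, lam=0.0)
        ref = _newton_logistic(X, y)
        assert b == pytest.approx(ref[0], abs=1e-4)
        assert np.allclose(w, ref[1:], atol=1e-4)

    def test_path_sparsity_monotone_in_lambda(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(150, 10))
        beta = np.array([2.0, -1.5, 1.0, 0, 0, 0, 0, 0, 0, 0])
        y = (rng.random(150) < expit(X @ beta)).astype(int)
        sig = lasso_logistic_cv(pd.DataFrame(X, columns=[f"f{i}" for i in range(10)]), y, folds=5, seed=0)
        # path stored dense at small lambda; nonzero count non-increasing in lambda
        assert np.all(np.diff(sig.nonzero_path) >= 0)

    def test_determinism_given_seed(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(80, 6)), columns=list("abcdef"))
        y = (rng.random(80) < 0.4).astype(int)
        a = lasso_logistic_cv(X, y, folds=5, seed=3)
        b = lasso_logistic_cv(X, y, folds=5, seed=3)
        assert a.features == b.features
        assert np.allclose(a.weights, b.weights)
        assert a.lam == b.lam


class TestRadscore:
    def test_empty_signature_is_constant(self):
        sig = Signature(features=[], weights=np.array([]), intercept=0.3, lam=1.0, empty=True)
        assert radscore({"anything": 5.0}, sig) == pytest.approx(0.3)

    def test_hand_arithmetic(self):
        sig = Signature(features=["a", "b"], weights=np.array([1.0, -2.0]), intercept=1.0, lam=0.1)
        assert radscore({"a": 2.0, "b": 0.5}, sig) == pytest.approx(2.0)

    def test_missing_feature_named_in_error(self):
        sig = Signature(features=["needed"], weights=np.array([1.0]), intercept=0.0, lam=0.1)
        with pytest.raises(KeyError, match="needed"):
            radscore({"other": 1.0}, sig)

    def test_equals_penalized_fit_linear_predictor(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(120, 5)), columns=list("abcde"))
        y = (rng.random(120) < expit(1.5 * X["a"] - X["b"])).astype(int)
        sig = lasso_logistic_cv(X, y, folds=5, seed=1)
        w, b, _ = fit_l1_at_lambda(X.to_numpy(), y, lam=sig.lam)
        lp = X.to_numpy() @ w + b
        assert np.allclose(radscore_table(X, sig).to_numpy(), lp, atol=1e-6)


class TestStepwiseAIC:
    def test_aic_equals_likelihood_arithmetic_on_toy(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0, 4.0, 5.0]})
        y = np.array([0, 0, 1, 0, 1, 1])
        params, aic, res = _fit_logit(X, y)
        p = expit(params["const"] + params["x"] * X["x"].to_numpy())
        ll = np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert aic == pytest.approx(2 * 2 - 2 * ll, abs=1e-6)

    def test_planted_effect_retained_null_dropped(self):
        rng = np.random.default_rng(10)
        n = 300
        signal = rng.normal(size=n)
        noise = rng.normal(size=n)
        y = (rng.random(n) < expit(2.0 * signal)).astype(int)
        design = pd.DataFrame({"signal": signal, "noise": noise})
        res = stepwise_aic_logistic(design, y)
        assert "signal" in res.terms
        assert "noise" not in res.terms

    def test_pure_noise_selects_almost_nothing(self):
        # AIC admits a noise variable with prob P(chi2_1 > 2) ~ 0.157, so with
        # 5 null candidates the intercept-only model appears in ~(0.843)^5 ~ 43%
        # of runs and >= 2 spurious terms are rare; assert both facts.
        n_terms = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n = 300
            design = pd.DataFrame(rng.normal(size=(n, 5)), columns=list("abcde"))
            y = (rng.random(n) < 0.4).astype(int)
            res = stepwise_aic_logistic(design, y)
            n_terms.append(len(res.terms))
        assert sum(c == 0 for c in n_terms) >= 2
        assert sum(c <= 1 for c in n_terms) >= 7

    def test_deterministic_given_input(self):
        rng = np.random.default_rng(11)
        design = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        y = (rng.random(100) < 0.5).astype(int)
        a = stepwise_aic_logistic(design, y)
        b = stepwise_aic_logistic(design, y)
        assert a.terms == b.terms
        assert np.allclose(a.params, b.params)


def _toy_cohort(seed=0, n=120):
    """Tabular mini-cohort with a planted habitat-fraction effect."""
    rng = np.random.default_rng(seed)
    rad = pd.DataFrame(
        rng.normal(size=(n, 8)), columns=[f"r{i}" for i in range(8)],
        index=[f"c{i}" for i in range(n)],
    )
    hab = pd.DataFrame(
        rng.normal(size=(n, 6)), columns=[f"h{i}" for i in range(6)],
        index=rad.index,
    )
    from conftest import make_clinical

    clin = pd.DataFrame([vars(make_clinical(rng)) for _ in range(n)], index=rad.index)
    lp = 1.5 * hab["h0"] - 1.0 * hab["h1"] + 0.8 * rad["r0"] - 0.02 * (clin["tumor_length"] - 51)
    y = (rng.random(n) < expit(lp - 0.5)).to_numpy().astype(int)
    return rad, hab, clin, y


class TestFiveModels:
    @pytest.fixture(scope="class")
    def fitted(self):
        rad, hab, clin, y = _toy_cohort()
        return fit_five_models(rad, hab, clin, y, seed=0, folds=5), (rad, hab, clin, y)

    def test_model_set_and_structure(self, fitted):
        models, _ = fitted
        assert set(models) == {"Clinic", "Radiomics", "Habitat", "Clinic+Radiomics", "Clinic+Habitat"}
        ch = models["Clinic+Habitat"]
        assert ch.terms == models["Clinic"].terms + ["score"]
        assert 0 < ch.threshold < 1
        for m in models.values():
            assert 0 < m.threshold < 1

    def test_combined_model_collapses_to_clinical_plus_one_score(self, fitted):
        models, _ = fitted
        cr = models["Clinic+Radiomics"]
        assert list(cr.params.index) == ["const"] + cr.terms
        assert cr.terms.count("score") == 1

    def test_refit_same_seed_identical(self, fitted):
        models, (rad, hab, clin, y) = fitted
        again = fit_five_models(rad, hab, clin, y, seed=0, folds=5)
        for mid in models:
            assert np.allclose(models[mid].params, again[mid].params)
            assert models[mid].threshold == again[mid].threshold

    def test_fitting_never_touches_test_rows(self):
        rad, hab, clin, y = _toy_cohort(seed=1)
        tr = rad.index[:80]
        te = rad.index[80:]
        models_clean = fit_five_models(rad.loc[tr], hab.loc[tr], clin.loc[tr], y[:80], seed=2, folds=5)
        # poison the held-out rows: identical fits prove no test-row access
        rad2, hab2, clin2 = rad.copy(), hab.copy(), clin.copy()
        rad2.loc[te] = 1e9
        hab2.loc[te] = -1e9
        clin2.loc[te, "tumor_length"] = 999.0
        models_poison = fit_five_models(rad2.loc[tr], hab2.loc[tr], clin2.loc[tr], y[:80], seed=2, folds=5)
        for mid in models_clean:
            assert np.allclose(models_clean[mid].params, models_poison[mid].params)

    def test_prediction_pipeline_applies_training_transforms(self, fitted):
        models, (rad, hab, clin, y) = fitted
        from habitatpipe.modeling import predict_model

        p = predict_model(models["Habitat"], rad, hab, clin)
        assert p.between(0, 1).all()
        # planted habitat effect should be learnable in-sample
        from habitatpipe.metrics import roc_auc

        assert roc_auc(p.to_numpy(), y) > 0.6


class TestClinicalDesign:
    def test_design_columns_and_coding(self):
        rng = np.random.default_rng(12)
        from conftest import make_clinical

        clin = pd.DataFrame([vars(make_clinical(rng)) for _ in range(20)])
        d = clinical_design(clin)
        assert "n_stage_N2" in d.columns and "sex_male" in d.columns
        assert set(np.unique(d["t_stage_T4"])) <= {0.0, 1.0}
        assert d.shape[1] == 17
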