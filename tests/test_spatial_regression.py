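import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from ecoweb.spatial_regression import (
    DEFAULT_PREDICTORS,
    DesignTable,
    FitResult,
    SpatialWeights,
    fit_ols,
    knn_weights,
    mem_eigenvectors,
    model_average,
    morans_test_residuals,
    run_regression_suite,
    select_best_aicc,
    sevm_select_filter,
    standardize_design,
    variable_importance,
)
from ecoweb.synthetic_data import SyntheticTruth, gen_site_table


@pytest.fixture(scope="module")
def design():
    _, d = gen_site_table(80, SyntheticTruth(betas={"n_species": 0.7, "T_mean": 0.3}, seed=21))
    return d


@pytest.fixture(scope="module")
def weights(design):
    return knn_weights(design.coords, k=6)


class TestStandardizeDesign:
    def test_columns_standardized(self, design):
        std = standardize_design(design)
        assert abs(std.response.mean()) < 1e-12
        for c in std.predictors.columns:
            assert abs(std.predictors[c].mean()) < 1e-12
            assert std.predictors[c].std(ddof=0) == pytest.approx(1.0)

    def test_idempotent(self, design):
        once = standardize_design(design)
        twice = standardize_design(once)
        pd.testing.assert_frame_equal(once.predictors, twice.predictors)

    def test_constant_column_named(self, design):
        bad = DesignTable(design.response, design.predictors.assign(elevation=1.0), design.coords)
        with pytest.raises(ValueError, match="elevation"):
            standardize_design(bad)


class TestFitOls:
    def test_exact_linear_response(self, design):
        y = 2.0 * design.predictors["n_species"] - design.predictors["T_mean"]
        noiseless = DesignTable(y.rename("y"), design.predictors, design.coords)
        fit = fit_ols(noiseless, ("n_species", "T_mean"))
        assert fit.r2 == pytest.approx(1.0)
        assert np.max(np.abs(fit.residuals)) < 1e-9

    def test_matches_statsmodels(self, design):
        std = standardize_design(design)
        terms = ("n_species", "T_mean", "human_impact")
        fit = fit_ols(std, terms)
        X = sm.add_constant(std.predictors[list(terms)].to_numpy())
        ref = sm.OLS(std.response.to_numpy(), X).fit()
        np.testing.assert_allclose(fit.params.to_numpy(), ref.params, atol=1e-9)
        np.testing.assert_allclose(fit.bse.to_numpy(), ref.bse, atol=1e-9)
        np.testing.assert_allclose(fit.pvalues.to_numpy(), ref.pvalues, atol=1e-9)
        assert fit.r2 == pytest.approx(ref.rsquared, abs=1e-12)
        assert fit.llf == pytest.approx(ref.llf, abs=1e-9)

    def test_aicc_correction_vanishes_for_large_n(self):
        rng = np.random.default_rng(0)
        n = 5000
        pred = pd.DataFrame(
            {name: rng.standard_normal(n) for name in DEFAULT_PREDICTORS}
        )
        y = pd.Series(rng.standard_normal(n), name="y")
        coords = np.column_stack([rng.uniform(0, 10, n), rng.uniform(0, 10, n)])
        fit = fit_ols(DesignTable(y, pred, coords), ("n_species",))
        k = 3  # intercept + slope + error variance
        aic = -2 * fit.llf + 2 * k
        assert fit.aicc - aic == pytest.approx(0.0, abs=0.01)

    def test_rank_deficient_rejected(self, design):
        dup = design.predictors.assign(T_copy=design.predictors["T_mean"])
        d = DesignTable(design.response, dup, design.coords)
        with pytest.raises(ValueError, match="rank"):
            fit_ols(d, ("T_mean", "T_copy"))


class TestModelSelection:
    def test_single_candidate_weight_one(self, design):
        models = select_best_aicc(design, ("n_species",))
        assert models.weights.sum() == pytest.approx(1.0)
        assert len(models.models) == 1

    def test_weights_for_delta_two(self):
        # two models with AICc difference 2 get weights 1/(1+e^-1), e^-1/(1+e^-1)
        w0 = 1.0 / (1.0 + np.exp(-1.0))
        assert w0 == pytest.approx(0.731, abs=1e-3)

    def test_weights_sum_to_one_and_ranked(self, design):
        models = select_best_aicc(design, ("T_mean", "human_impact", "elevation"))
        assert models.weights.sum() == pytest.approx(1.0)
        aiccs = [m.aicc for m in models.models]
        assert aiccs == sorted(aiccs)
        assert len(models.models) == 8

    def test_fixed_term_in_every_model(self, design):
        models = select_best_aicc(design, ("T_mean", "elevation"))
        assert all("n_species" in m.terms for m in models.models)


class TestImportanceAndAveraging:
    def test_fixed_term_importance_one(self, design):
        models = select_best_aicc(design, ("T_mean", "elevation"))
        imp = variable_importance(models)
        assert imp["n_species"] == pytest.approx(1.0)
        assert ((imp >= 0) & (imp <= 1.0 + 1e-12)).all()

    def test_importance_matches_hand_sum(self, design):
        models = select_best_aicc(design, ("T_mean", "elevation"))
        imp = variable_importance(models)
        hand = sum(w for m, w in zip(models.models, models.weights) if "T_mean" in m.terms)
        assert imp["T_mean"] == pytest.approx(hand)

    def test_confidence_set_of_one(self, design):
        models = select_best_aicc(design, ("T_mean",))
        avg = model_average(models, conf=1e-9)
        best = models.best
        for term in ("intercept", "n_species"):
            assert avg.loc[term, "estimate"] == pytest.approx(best.params[term])

    def test_conditional_average_weighted_mean(self):
        # two models, weights 0.6/0.4, betas 1.0/2.0 -> conditional average 1.4
        betas = np.array([1.0, 2.0])
        w = np.array([0.6, 0.4])
        assert float(w @ betas) == pytest.approx(1.4)

    def test_full_average_shrinks_toward_zero(self, design):
        models = select_best_aicc(design, ("T_mean", "elevation", "P_ann"))
        cond = model_average(models, method="conditional")
        full = model_average(models, method="full")
        # a weak term appears in few models: zero-substitution can only shrink
        assert abs(full.loc["P_ann", "estimate"]) <= abs(cond.loc["P_ann", "estimate"]) + 1e-12


class TestMoranTest:
    def test_checkerboard_rook_grid_is_minus_one(self):
        W = np.array([[0, 1, 1, 0], [1, 0, 0, 1], [1, 0, 0, 1], [0, 1, 1, 0]], dtype=float)
        y = np.array([1.0, 0.0, 0.0, 1.0])
        fit = FitResult(
            terms=(),
            params=pd.Series([y.mean()], index=["intercept"]),
            bse=pd.Series([0.0], index=["intercept"]),
            pvalues=pd.Series([1.0], index=["intercept"]),
            r2=0.0,
            llf=0.0,
            aicc=0.0,
            residuals=y - y.mean(),
            design_matrix=np.ones((4, 1)),
        )
        res = morans_test_residuals(fit, SpatialWeights(W, "binary"))
        assert res.I == pytest.approx(-1.0, abs=1e-12)

    def test_constant_residuals_rejected(self):
        fit = FitResult(
            terms=(),
            params=pd.Series([0.0], index=["intercept"]),
            bse=pd.Series([0.0], index=["intercept"]),
            pvalues=pd.Series([1.0], index=["intercept"]),
            r2=0.0,
            llf=0.0,
            aicc=0.0,
            residuals=np.zeros(4),
            design_matrix=np.ones((4, 1)),
        )
        W = SpatialWeights(1.0 - np.eye(4), "binary")
        with pytest.raises(ValueError, match="residual"):
            morans_test_residuals(fit, W)

    def test_permutation_p_agrees_with_normal_p(self, design, weights):
        fit = fit_ols(standardize_design(design), DEFAULT_PREDICTORS)
        normal = morans_test_residuals(fit, weights)
        perm = morans_test_residuals(fit, weights, permutations=999, seed=1)
        assert (normal.p < 0.05) == (perm.p < 0.05)


class TestSpatialWeights:
    def test_row_standardized_rows_sum_to_one(self, weights):
        np.testing.assert_allclose(weights.matrix.sum(axis=1), 1.0)
        assert np.all(np.diag(weights.matrix) == 0)

    def test_k_neighbors_each_row(self, design):
        w = knn_weights(design.coords, k=4, style="binary")
        np.testing.assert_array_equal(w.matrix.sum(axis=1), 4.0)


class TestMemEigenvectors:
    def test_mean_zero_unit_norm_orthogonal(self, weights):
        _, vecs = mem_eigenvectors(weights)
        assert np.max(np.abs(vecs.mean(axis=0))) < 1e-10
        gram = vecs.T @ vecs
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-10)

    def test_ring_graph_leading_vectors_are_sinusoids(self):
        n = 24
        W = np.zeros((n, n))
        for i in range(n):
            W[i, (i + 1) % n] = W[i, (i - 1) % n] = 1.0
        vals, vecs = mem_eigenvectors(SpatialWeights(W, "binary"))
        # leading eigenvalue of the centered circulant is 2cos(2*pi/n), twice degenerate
        assert vals[0] == pytest.approx(2 * np.cos(2 * np.pi / n), abs=1e-9)
        assert vals[1] == pytest.approx(vals[0], abs=1e-9)
        # the leading eigenspace is spanned by cos/sin of the fundamental frequency
        t = 2 * np.pi * np.arange(n) / n
        basis = np.column_stack([np.cos(t), np.sin(t)])
        proj = basis @ np.linalg.lstsq(basis, vecs[:, :2], rcond=None)[0]
        np.testing.assert_allclose(proj, vecs[:, :2], atol=1e-8)


class TestSevm:
    def test_independent_errors_select_few_vectors(self):
        empty_or_tiny = 0
        for s in range(10):
            _, d = gen_site_table(
                60, SyntheticTruth(betas={}, error_spatial_share=0.0, seed=300 + s)
            )
            w = knn_weights(d.coords, k=6)
            filt = sevm_select_filter(standardize_design(d), DEFAULT_PREDICTORS, w)
            empty_or_tiny += len(filt) <= 2
        assert empty_or_tiny >= 9

    def test_filter_never_increases_moran(self, design, weights):
        std = standardize_design(design)
        filt = sevm_select_filter(std, DEFAULT_PREDICTORS, weights)
        base = morans_test_residuals(fit_ols(std, DEFAULT_PREDICTORS), weights)
        _, vecs = mem_eigenvectors(weights)
        fv = vecs[:, list(filt)] if filt else None
        after = morans_test_residuals(fit_ols(std, DEFAULT_PREDICTORS, fv, filt), weights)
        assert abs(after.z) <= abs(base.z) + 1e-9


class TestSuite:
    def test_table_structure_and_determinism(self, design, weights):
        s1 = run_regression_suite(design, weights)
        s2 = run_regression_suite(design, weights)
        t1, t2 = s1.to_table(), s2.to_table()
        pd.testing.assert_frame_equal(t1, t2)
        assert list(t1.columns) == [
            "OLS_full",
            "OLS_best",
            "OLS_averaged",
            "OLS_importance",
            "SEVM_full",
            "SEVM_best",
            "SEVM_averaged",
            "SEVM_importance",
        ]
        assert list(t1.index[:9]) == list(DEFAULT_PREDICTORS)
        assert list(t1.index[-2:]) == ["Moran_I", "R2"]

    def test_ols_and_sevm_agree_without_spatial_error(self):
        _, d = gen_site_table(
            80,
            SyntheticTruth(betas={"n_species": 0.7}, error_spatial_share=0.0, seed=77),
        )
        w = knn_weights(d.coords, k=6)
        suite = run_regression_suite(d, w)
        b_ols = suite.ols_full.params["n_species"]
        b_sevm = suite.sevm_full.params["n_species"]
        se = suite.ols_full.bse["n_species"]
        assert abs(b_ols - b_sevm) < 2 * se
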