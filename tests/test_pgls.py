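"""GLS core, profile-lambda PGLS, AICc machinery and model selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polymort.pgls import (
    ModelComparison,
    ModelSpec,
    SingularModelError,
    aicc,
    akaike_weights,
    check_normality,
    compare_models,
    gls_fit,
    profile_lambda,
    select_model,
)
from polymort.phylo import CovarianceMatrix, lambda_transform, vcv
from polymort.synthetic import TraitTruth, simulate_traits, simulate_tree


def identity_cov(n):
    return CovarianceMatrix(tuple(f"t{i}" for i in range(n)), np.eye(n))


class TestGlsFit:
    def test_identity_covariance_reduces_to_ols(self, rng):
        n = 25
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        y = X @ [1.0, 2.0, -0.5] + rng.normal(size=n)
        res = gls_fit(y, X, identity_cov(n))
        beta, resid, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(res.beta, beta, atol=1e-10)
        rss = float(np.sum((y - X @ beta) ** 2))
        se = np.sqrt(np.diag(rss / (n - 3) * np.linalg.inv(X.T @ X)))
        np.testing.assert_allclose(res.se, se, atol=1e-10)
        np.testing.assert_allclose(res.t_stat, beta / se, atol=1e-10)

    def test_perfect_fit_flagged(self, rng):
        n = 8
        X = np.column_stack([np.ones(n), np.arange(n, dtype=float)])
        y = X @ [0.5, 2.0]
        res = gls_fit(y, X, identity_cov(n))
        assert res.zero_residuals
        assert res.sigma2 == pytest.approx(0.0, abs=1e-20)

    def test_loglik_equals_mvn_density(self, rng):
        for seed in range(5):
            tree = simulate_tree(6, seed=seed)
            cov = vcv(tree)
            r = np.random.default_rng(seed)
            X = np.column_stack([np.ones(6), r.normal(size=6)])
            y = r.normal(size=6)
            res = gls_fit(y, X, cov)
            direct = stats.multivariate_normal.logpdf(
                y, X @ res.beta, res.sigma2 * cov.V
            )
            assert res.logLik == pytest.approx(direct, abs=1e-8)

    def test_collinear_design_rejected(self, rng):
        n = 10
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x, 2 * x])
        with pytest.raises(SingularModelError, match="collinear"):
            gls_fit(rng.normal(size=n), X, identity_cov(n))


class TestProfileLambda:
    def test_star_tree_lambda_unidentifiable_returns_zero(self, star_tree, rng):
        cov = vcv(star_tree)
        y = rng.normal(size=10)
        fit = profile_lambda(y, np.ones((10, 1)), cov)
        assert fit.lambda_hat == 0.0

    def test_independent_noise_on_deep_tree_gives_small_lambda(self):
        tree = simulate_tree(100, seed=17)
        cov = vcv(tree)
        r = np.random.default_rng(17)
        y = r.normal(size=100)
        X = np.column_stack([np.ones(100), r.normal(size=100)])
        fit = profile_lambda(y, X, cov)
        assert fit.lambda_hat < 0.15

    def test_matches_fine_grid_search(self):
        tree = simulate_tree(40, seed=23)
        truth = TraitTruth(beta=(1.0,), lambda_true=0.6, sigma2=0.5, n_tips=40, seed=23)
        tr = simulate_traits(tree, truth)
        y = np.log(tr["y"].to_numpy())
        X = np.column_stack([np.ones(40), np.log(tr["x1"].to_numpy())])
        cov = vcv(tree).reorder(list(tr["species"]))
        fit = profile_lambda(y, X, cov)
        grid = np.arange(0, 1.0001, 0.001)
        lls = np.array([gls_fit(y, X, lambda_transform(cov, g)).logLik for g in grid])
        assert abs(grid[lls.argmax()] - fit.lambda_hat) <= 0.002
        assert abs(lls.max() - fit.logLik) <= 1e-4

    def test_optimum_dominates_coarse_grid(self):
        tree = simulate_tree(30, seed=31)
        truth = TraitTruth(beta=(0.5,), lambda_true=0.8, sigma2=1.0, n_tips=30, seed=31)
        tr = simulate_traits(tree, truth)
        y = np.log(tr["y"].to_numpy())
        X = np.column_stack([np.ones(30), np.log(tr["x1"].to_numpy())])
        cov = vcv(tree).reorder(list(tr["species"]))
        fit = profile_lambda(y, X, cov)
        for lam in np.arange(0, 1.01, 0.1):
            assert fit.logLik >= gls_fit(y, X, lambda_transform(cov, lam)).logLik - 1e-9

    def test_lambda_zero_fit_equals_diagonal_rescaled_ols(self):
        tree = simulate_tree(20, seed=5)
        cov = vcv(tree)
        r = np.random.default_rng(5)
        y = r.normal(size=20)
        X = np.column_stack([np.ones(20), r.normal(size=20)])
        res0 = gls_fit(y, X, lambda_transform(cov, 0.0))
        W = np.diag(1.0 / np.sqrt(np.diag(cov.V)))
        beta_ols = np.linalg.lstsq(W @ X, W @ y, rcond=None)[0]
        np.testing.assert_allclose(res0.beta, beta_ols, atol=1e-8)


class TestAicc:
    def test_hand_arithmetic(self):
        assert aicc(-50.0, 4, 48) == pytest.approx(108 + 40 / 43)

    def test_large_n_limit_is_aic(self):
        assert aicc(0.0, 3, 10**7) == pytest.approx(6.0, abs=1e-4)

    def test_correction_identity(self):
        for k, n in ((3, 48), (5, 20), (7, 51)):
            assert aicc(-10.0, k, n) - (20 + 2 * k) == pytest.approx(
                2 * k * (k + 1) / (n - k - 1)
            )

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="n="):
            aicc(-10.0, 5, 6)


class TestAkaikeWeights:
    def test_published_delta_column_reproduced(self):
        # carnivore lifespan candidate set: printed weights 0.43/0.41/...
        w = akaike_weights([0.00, 0.09, 2.34, 6.52, 8.72, 12.60])
        np.testing.assert_allclose(w, [0.43, 0.41, 0.13, 0.02, 0.01, 0.00], atol=0.005)

    def test_single_model_gets_unit_weight(self):
        assert akaike_weights([0.0]) == pytest.approx([1.0])

    def test_tied_models_split_evenly(self):
        np.testing.assert_allclose(akaike_weights([0.0, 0.0]), [0.5, 0.5])

    def test_sum_one_and_monotone(self, rng):
        for _ in range(20):
            d = np.sort(np.concatenate([[0.0], rng.uniform(0, 20, size=5)]))
            w = akaike_weights(d)
            assert w.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(np.diff(w) <= 1e-15)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            akaike_weights([])


def comparison_from(aiccs, ks):
    t = pd.DataFrame(
        {
            "label": [f"m{i}" for i in range(len(aiccs))],
            "k": ks,
            "aicc": aiccs,
            "delta_aicc": np.asarray(aiccs) - min(aiccs),
        }
    )
    return ModelComparison(table=t)


class TestSelectModel:
    def test_parsimony_retains_simplest_within_window(self):
        # printed multiple-paternity aging-rate set: constant (k=3) within
        # 2 units of the litter-size model (k=4) -> constant retained
        aiccs = [48.88, 52.61, 51.96, 49.39, 53.63, 58.40, 54.00, 55.58, 61.31]
        ks = [3, 4, 4, 4, 5, 5, 5, 6, 7]
        assert select_model(comparison_from(aiccs, ks)) == 0

    def test_single_row(self):
        assert select_model(comparison_from([10.0], [4])) == 0

    def test_competitor_outside_window_ignored(self):
        assert select_model(comparison_from([100.0, 105.0], [5, 3])) == 0

    def test_invariant_to_constant_shift(self, rng):
        aiccs = list(rng.uniform(50, 70, size=6))
        ks = [3, 4, 4, 5, 6, 7]
        base = select_model(comparison_from(aiccs, ks))
        shifted = select_model(comparison_from([a + 123.4 for a in aiccs], ks))
        assert base == shifted


class TestAdjustedR2:
    def test_intercept_only_reports_zero(self, rng):
        n = 20
        y = rng.normal(size=n)
        fit = profile_lambda(y, np.ones((n, 1)), identity_cov(n))
        assert fit.r2_adj == pytest.approx(0.0)

    def test_matches_textbook_ols_adjusted_r2(self, rng):
        n = 30
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        y = X @ [0.5, 1.0, -2.0] + rng.normal(size=n)
        fit = profile_lambda(y, X, identity_cov(n))
        yhat = X @ np.linalg.lstsq(X, y, rcond=None)[0]
        r2 = 1 - np.sum((y - yhat) ** 2) / np.sum((y - y.mean()) ** 2)
        adj = 1 - (1 - r2) * (n - 1) / (n - 3)
        assert fit.r2_adj == pytest.approx(adj, abs=1e-8)


class TestModelSpec:
    def test_interaction_requires_main_effects(self):
        with pytest.raises(ValueError, match="main effects"):
            ModelSpec("y", ("a",), interactions=(("a", "b"),))

    def test_k_counts_coefficients_plus_variance_and_lambda(self):
        assert ModelSpec("y").k == 3
        assert ModelSpec("y", ("a",)).k == 4
        assert ModelSpec("y", ("a", "b", "c"), interactions=(("a", "b"),)).k == 7


class TestCheckNormality:
    def test_lognormal_sample_flagged_for_transform(self):
        r = np.random.default_rng(3)
        p, flag = check_normality(np.exp(r.normal(0, 1, size=50)))
        assert flag and p < 0.05

    def test_gaussian_samples_rarely_flagged(self):
        flags = []
        for seed in range(40):
            r = np.random.default_rng(seed)
            _, flag = check_normality(r.normal(size=50))
            flags.append(flag)
        assert sum(flags) <= 6  # nominal 5% type-I rate

    def test_tiny_or_constant_samples_rejected(self):
        with pytest.raises(ValueError):
            check_normality([1.0, 2.0])
        with pytest.raises(ValueError):
            check_normality([1.0, 1.0, 1.0, 1.0])


class TestExternalOracle:
    def test_matches_r_ape_corpagel_ml_fit(self, tmp_path):
        """Coefficients, ML λ and logLik agree with an independent PGLS
        implementation (R: nlme::gls with ape::corPagel) on a fixed dataset
        whose λ optimum is interior."""
        import subprocess

        tree = simulate_tree(30, seed=99)
        truth = TraitTruth(beta=(1.0,), lambda_true=0.6, sigma2=0.5, n_tips=30, seed=99)
        tr = simulate_traits(tree, truth)
        tr["log_y"] = np.log(tr["y"])
        tr["log_x"] = np.log(tr["x1"])
        dat = tmp_path / "dat.csv"
        nwk = tmp_path / "tree.nwk"
        tr[["species", "log_y", "log_x"]].to_csv(dat, index=False)
        tree.write_newick(nwk)

        cov = vcv(tree).reorder(list(tr["species"]))
        X = np.column_stack([np.ones(30), tr["log_x"].to_numpy()])
        fit = profile_lambda(tr["log_y"].to_numpy(), X, cov)

        script = f"""
        suppressMessages({{library(ape); library(nlme)}})
        d <- read.csv("{dat}"); tr <- read.tree("{nwk}")
        rownames(d) <- d$species; d <- d[tr$tip.label,]
        f <- gls(log_y ~ log_x, data=d,
                 correlation=corPagel(0.5, phy=tr, form=~species), method="ML")
        cat(coef(f), coef(f$modelStruct$corStruct, unconstrained=FALSE),
            logLik(f), sep="\\n")
        """
        out = subprocess.run(
            ["Rscript", "-"], input=script, capture_output=True, text=True, check=True
        )
        b0, b1, lam, ll = map(float, out.stdout.strip().splitlines()[-4:])
        np.testing.assert_allclose(fit.beta, [b0, b1], atol=1e-5)
        assert fit.lambda_hat == pytest.approx(lam, abs=1e-4)
        assert fit.logLik == pytest.approx(ll, abs=1e-5)


class TestCompareModels:
    def test_weights_and_selection_consistent(self):
        tree = simulate_tree(30, seed=8)
        truth = TraitTruth(beta=(1.0,), lambda_true=0.5, sigma2=0.3, n_tips=30, seed=8)
        tr = simulate_traits(tree, truth, predictor_names=("x1",))
        df = pd.DataFrame(
            {
                "species": tr["species"],
                "y": np.log(tr["y"].to_numpy()),
                "x1": np.log(tr["x1"].to_numpy()),
            }
        )
        cov = vcv(tree).reorder(list(df["species"]))
        fits = []
        for spec in (ModelSpec("y"), ModelSpec("y", ("x1",))):
            X, names = spec.design_matrix(df)
            fits.append(
                profile_lambda(df["y"].to_numpy(), X, cov, spec=spec, term_names=names)
            )
        cmp = compare_models(fits)
        assert cmp.table["weight"].sum() == pytest.approx(1.0)
        assert cmp.table["delta_aicc"].min() == 0.0
        assert cmp.selected == 1  # strong true slope: predictor model retained
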