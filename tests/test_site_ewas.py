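"""Site-level models: OLS oracle equivalence, moderation, lambda, BH."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methsev.site_ewas import (
    adjust_fdr,
    build_design_matrix,
    estimate_prior,
    fit_site_models,
    genomic_inflation,
    moderate_variances,
    rank_and_annotate,
)


def _design_from(samples, **kw):
    return build_design_matrix(samples, **kw)


def _random_problem(rng, n=50, n_sites=20, p_extra=3):
    X = pd.DataFrame(
        np.column_stack([
            np.ones(n), rng.standard_normal((n, p_extra)), rng.poisson(6.6, n)
        ]),
        columns=["intercept"] + [f"c{i}" for i in range(p_extra)] + ["severity"],
        index=[f"S{j}" for j in range(n)],
    )
    Y = pd.DataFrame(
        rng.standard_normal((n_sites, n)),
        index=[f"cg{i}" for i in range(n_sites)],
        columns=X.index,
    )
    return Y, X


class TestFitSiteModels:
    def test_noiseless_site_recovers_slope_exactly(self, rng):
        Y, X = _random_problem(rng)
        Y.iloc[0] = 0.5 * X["severity"].to_numpy()
        fits = fit_site_models(Y, X)
        assert fits.iloc[0]["beta"] == pytest.approx(0.5, abs=1e-10)
        assert fits.iloc[0]["s2"] == pytest.approx(0.0, abs=1e-18)

    def test_orthogonal_site_gives_zero_beta(self, rng):
        Y, X = _random_problem(rng)
        # residualize a site against the severity column exactly
        A = X.to_numpy()
        Q, _ = np.linalg.qr(A)
        v = rng.standard_normal(len(X))
        v -= Q @ (Q.T @ v)  # orthogonal to the whole design
        Y.iloc[0] = v
        fits = fit_site_models(Y, X)
        assert abs(fits.iloc[0]["beta"]) < 1e-10

    def test_matches_normal_equations_oracle(self, rng):
        Y, X = _random_problem(rng, n=50, n_sites=30)
        fits = fit_site_models(Y, X)
        A = X.to_numpy()
        XtX_inv = np.linalg.inv(A.T @ A)  # independent normal-equations route
        H = XtX_inv @ A.T
        for i in range(len(Y)):
            y = Y.iloc[i].to_numpy()
            beta = H @ y
            resid = y - A @ beta
            s2 = resid @ resid / (len(y) - A.shape[1])
            se = np.sqrt(s2 * XtX_inv[-1, -1])
            assert fits.iloc[i]["beta"] == pytest.approx(beta[-1], abs=1e-8)
            assert fits.iloc[i]["se"] == pytest.approx(se, abs=1e-8)

    def test_df_residual(self, rng):
        Y, X = _random_problem(rng, n=40)
        fits = fit_site_models(Y, X)
        assert (fits["df_residual"] == 40 - X.shape[1]).all()


class TestDesignMatrix:
    def test_aliased_batch_dropped_with_warning(self, small_dataset, caplog):
        samples = small_dataset.samples.copy()
        samples["batch_const"] = "only_level"  # dummies drop_first -> nothing
        samples["cell_dup"] = samples["cell_Neu"]
        X = build_design_matrix(samples)
        assert np.linalg.matrix_rank(X.to_numpy()) == X.shape[1]
        assert X.columns[-1] == "severity"

    def test_missing_severity_rejected(self, small_dataset):
        with pytest.raises(KeyError):
            build_design_matrix(small_dataset.samples.drop(columns=["severity"]))


class TestModeration:
    def test_tight_variances_approach_pooled(self, rng):
        n_sites, df = 500, 30
        beta = rng.standard_normal(n_sites)
        s2 = np.full(n_sites, 0.25) * (1 + rng.normal(0, 1e-4, n_sites))
        fits = pd.DataFrame({
            "beta": beta, "se": np.sqrt(s2 * 0.01), "s2": s2,
            "df_residual": df,
        })
        prior, out = moderate_variances(fits)
        assert prior.d0 > 1e4 or np.isinf(prior.d0)
        # ranking by |t_mod| equals ranking by |beta|
        r1 = np.argsort(np.abs(out["t_mod"]))
        r2 = np.argsort(np.abs(beta / np.sqrt(0.01)))
        assert list(r1) == list(r2)

    def test_heavy_tailed_variances_approach_ordinary_t(self, rng):
        df = 20
        s2 = np.exp(rng.normal(0, 3, 2000))  # enormous spread -> d0 ~ 0
        beta = rng.standard_normal(2000)
        fits = pd.DataFrame({
            "beta": beta, "se": np.sqrt(s2 * 0.02), "s2": s2, "df_residual": df,
        })
        prior, out = moderate_variances(fits)
        assert prior.d0 < 1.0
        t_ord = (fits["beta"] / fits["se"]).to_numpy()
        rel = np.abs(out["t_mod"].to_numpy() - t_ord) / np.abs(t_ord)
        # shrinkage vanishes except at the extreme-variance tails
        assert np.median(rel) < 0.02
        assert np.quantile(rel, 0.75) < 0.10

    def test_null_type_one_error_calibrated(self, rng):
        # 5,000 null sites, n = 30: rejection rate at alpha=0.05 in [0.04, 0.06]
        n, m = 30, 5000
        X = pd.DataFrame(
            np.column_stack([np.ones(n), rng.poisson(6.6, n)]),
            columns=["intercept", "severity"],
            index=[f"S{j}" for j in range(n)],
        )
        Y = pd.DataFrame(rng.standard_normal((m, n)) * rng.uniform(0.5, 2, (m, 1)),
                         index=[f"cg{i}" for i in range(m)], columns=X.index)
        fits = fit_site_models(Y, X)
        _, out = moderate_variances(fits)
        rate = float((out["p"] < 0.05).mean())
        assert 0.04 <= rate <= 0.06

    def test_scaled_f_prior_recovery(self, rng):
        # s2 drawn from the scaled-F model: moment estimator recovers (d0, s0)
        d0_true, s0_true, df = 8.0, 0.3, 25
        m = 20000
        s2 = s0_true * (stats.chi2.rvs(df, size=m, random_state=1) / df) / (
            stats.chi2.rvs(d0_true, size=m, random_state=2) / d0_true
        )
        prior = estimate_prior(s2, df)
        assert prior.d0 == pytest.approx(d0_true, rel=0.15)
        assert prior.s0_sq == pytest.approx(s0_true, rel=0.05)

    def test_degenerate_all_zero_rejected(self):
        fits = pd.DataFrame({
            "beta": [0.0] * 12, "se": [0.0] * 12, "s2": [0.0] * 12,
            "df_residual": 10,
        })
        with pytest.raises(ValueError):
            moderate_variances(fits)


class TestGenomicInflation:
    def test_all_half_gives_unity(self):
        assert genomic_inflation(np.full(1001, 0.5)) == pytest.approx(1.0)

    def test_uniform_p_gives_unity(self, rng):
        p = rng.uniform(0, 1, 100_000)
        p = np.clip(p, 1e-12, 1.0)
        assert 0.98 <= genomic_inflation(p) <= 1.02

    def test_more_significant_p_increases_lambda(self, rng):
        p = rng.uniform(0.01, 1, 5000)
        assert genomic_inflation(p / 2) > genomic_inflation(p)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            genomic_inflation(np.array([]))


class TestBenjaminiHochberg:
    def test_textbook_example(self):
        q = adjust_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    @pytest.mark.parametrize("p,expected", [
        ([0.5], [0.5]),
        ([1.0, 1.0], [1.0, 1.0]),
    ])
    def test_degenerate_vectors(self, p, expected):
        np.testing.assert_allclose(adjust_fdr(np.array(p)), expected)

    def test_against_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 500)
        _, q_sm, *_ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(adjust_fdr(p), q_sm, atol=1e-12)

    def test_monotone_in_rank(self, rng):
        p = rng.uniform(0, 1, 200)
        q = adjust_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestRankAndAnnotate:
    def test_sort_and_tie_break(self, toy_manifest):
        res = pd.DataFrame(
            {"beta": [0.1, -0.2, 0.3], "p": [1e-6, 1e-7, 1e-6]},
            index=pd.Index(["cg05", "cg01", "cg02"], name="site_id"),
        )
        out = rank_and_annotate(res, toy_manifest)
        assert list(out["site_id"]) == ["cg01", "cg02", "cg05"]
        assert list(out["rank"]) == [1, 2, 3]
        assert out.loc[out.site_id == "cg05", "gene"].iloc[0] == "GENE2"

    def test_unmapped_site_flagged(self, toy_manifest):
        res = pd.DataFrame(
            {"beta": [0.1], "p": [0.5]},
            index=pd.Index(["cg_missing"], name="site_id"),
        )
        out = rank_and_annotate(res, toy_manifest)
        assert out.loc[0, "gene"] == "unmapped"


def test_classical_ols_limit_of_pipeline(rng):
    """With the prior pinned near zero, moderated t equals the classical t."""
    from methsev.site_ewas import ModerationParams

    Y, X = _random_problem(rng, n=40, n_sites=100)
    fits = fit_site_models(Y, X)
    prior = ModerationParams(d0=1e-9, s0_sq=1.0)
    _, out = moderate_variances(fits, prior=prior)
    t_ord = fits["beta"] / fits["se"]
    np.testing.assert_allclose(out["t_mod"], t_ord, atol=1e-8)
    p_ord = 2 * stats.t.sf(np.abs(t_ord), fits["df_residual"].iloc[0])
    np.testing.assert_allclose(out["p"], p_ord, atol=1e-6)
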