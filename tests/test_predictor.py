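"""Split, pooling, PLS/elastic-net fits, frozen-model prediction, ROC."""

import numpy as np
import pandas as pd
import pytest

from methsev.predictor import (
    PredictorModel,
    fit_latent_regression,
    fit_sparse_subset,
    pool_significant_sites,
    predict_and_correlate,
    roc_analysis,
    split_cohort,
)
from methsev.region_ewas import RegionDefinition


class TestSplit:
    def test_even_half_split(self):
        ids = [f"S{i}" for i in range(232)]
        split = split_cohort(ids, seed=1)
        assert len(split.discovery_ids) == 116
        assert len(split.validation_ids) == 116
        assert set(split.discovery_ids) | set(split.validation_ids) == set(ids)
        assert set(split.discovery_ids) & set(split.validation_ids) == set()

    def test_odd_split_larger_discovery(self):
        split = split_cohort([f"S{i}" for i in range(233)], seed=0)
        assert len(split.discovery_ids) == 117
        assert len(split.validation_ids) == 116

    def test_deterministic_per_seed(self):
        ids = [f"S{i}" for i in range(50)]
        assert split_cohort(ids, 7) == split_cohort(ids, 7)
        assert split_cohort(ids, 7) != split_cohort(ids, 8)


class TestPooling:
    def _regions(self):
        return [
            RegionDefinition("isl_1", "island", ("cgA", "cgB", "cgC", "cgD"),
                             "G1", "1", 10, 40),
            RegionDefinition("isl_2", "island", ("cgX",), "G2", "2", 5, 5),
        ]

    def test_union_arithmetic(self):
        site_res = pd.DataFrame({
            "site_id": [f"cg{i:02d}" for i in range(10)] + ["cgA"],
            "q": [0.01] * 10 + [0.01],
        })
        region_res = pd.DataFrame({
            "region_id": ["isl_1", "isl_2"], "q": [0.01, 0.9],
        })
        pool = pool_significant_sites(site_res, region_res, self._regions())
        # 10 significant sites + cgA (shared) + 3 more island members = 14
        assert len(pool) == 14
        assert pool == sorted(pool)

    def test_no_significant_regions(self):
        site_res = pd.DataFrame({"site_id": ["cg1", "cg2"], "q": [0.01, 0.02]})
        region_res = pd.DataFrame({"region_id": ["isl_1"], "q": [0.5]})
        pool = pool_significant_sites(site_res, region_res, self._regions())
        assert pool == ["cg1", "cg2"]

    def test_idempotent(self):
        site_res = pd.DataFrame({"site_id": ["cg1"], "q": [0.001]})
        region_res = pd.DataFrame({"region_id": [], "q": []})
        p1 = pool_significant_sites(site_res, region_res, [])
        p2 = pool_significant_sites(
            pd.DataFrame({"site_id": p1, "q": [0.001] * len(p1)}),
            region_res, [],
        )
        assert p1 == p2

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            pool_significant_sites(
                pd.DataFrame({"site_id": ["cg1"], "q": [0.9]}),
                pd.DataFrame({"region_id": [], "q": []}), [],
            )


class TestLatentRegression:
    def test_single_feature_equals_simple_regression(self, rng):
        n = 40
        x = rng.standard_normal(n)
        y = 2.0 + 1.5 * x + rng.normal(0, 0.1, n)
        X = pd.DataFrame([x], index=["cg1"],
                         columns=[f"S{j}" for j in range(n)])
        ys = pd.Series(y, index=X.columns)
        model = fit_latent_regression(X, ys, k=1)
        pred = model.predict(X)
        slope, intercept = np.polyfit(x, y, 1)
        np.testing.assert_allclose(pred, intercept + slope * x, atol=1e-10)

    def test_orthogonal_outcome_gives_null_r2(self, rng):
        n = 30
        X = pd.DataFrame(rng.standard_normal((3, n)),
                         index=["a", "b", "c"],
                         columns=[f"S{j}" for j in range(n)])
        # build y orthogonal to every centered feature
        Z = X.to_numpy().T
        Zc = Z - Z.mean(axis=0)
        Q, _ = np.linalg.qr(np.column_stack([np.ones(n), Zc]))
        y = rng.standard_normal(n)
        y -= Q @ (Q.T @ y)
        ys = pd.Series(y, index=X.columns)
        model = fit_latent_regression(X, ys, k=2)
        pred = model.predict(X).to_numpy()
        ss_res = np.sum((y - pred) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert 1 - ss_res / ss_tot < 1e-10

    def test_duplicated_feature_columns_leave_predictions_unchanged(self, rng):
        n, m = 50, 6
        X = pd.DataFrame(rng.standard_normal((m, n)),
                         index=[f"cg{i}" for i in range(m)],
                         columns=[f"S{j}" for j in range(n)])
        y = pd.Series(X.iloc[0] * 0.5 + rng.normal(0, 0.2, n), index=X.columns)
        m1 = fit_latent_regression(X, y, k=3)
        X_dup = pd.concat([X, X.rename(index=lambda s: s + "_dup")])
        m2 = fit_latent_regression(X_dup, y, k=3)
        np.testing.assert_allclose(
            m1.predict(X), m2.predict(X_dup), atol=1e-8
        )

    def test_frozen_model_json_round_trip(self, rng, tmp_path):
        n, m = 30, 5
        X = pd.DataFrame(rng.standard_normal((m, n)),
                         index=[f"cg{i}" for i in range(m)],
                         columns=[f"S{j}" for j in range(n)])
        y = pd.Series(rng.standard_normal(n), index=X.columns)
        model = fit_latent_regression(X, y, k=2)
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = PredictorModel.from_json(path)
        np.testing.assert_allclose(loaded.predict(X), model.predict(X),
                                   atol=1e-12)

    def test_component_count_bounds(self, rng):
        X = pd.DataFrame(rng.standard_normal((4, 10)),
                         index=list("abcd"),
                         columns=[f"S{j}" for j in range(10)])
        y = pd.Series(rng.standard_normal(10), index=X.columns)
        with pytest.raises(ValueError):
            fit_latent_regression(X, y, k=9)


class TestSparseSubset:
    def test_soft_threshold_closed_form(self, rng):
        # single standardized feature, pure lasso at fixed penalty
        from sklearn.linear_model import ElasticNet

        n = 200
        x = rng.standard_normal(n)
        x = (x - x.mean()) / x.std(ddof=0)
        y = 0.4 * x + rng.normal(0, 0.5, n)
        yc = y - y.mean()
        rho = float(x @ yc / n)
        for lam in (0.05, 0.2, abs(rho) + 0.1):
            en = ElasticNet(alpha=lam, l1_ratio=1.0, fit_intercept=False)
            en.fit(x[:, None], yc)
            expected = np.sign(rho) * max(abs(rho) - lam, 0.0)
            assert en.coef_[0] == pytest.approx(expected, abs=1e-6)

    def test_penalty_to_zero_limit_matches_least_squares(self, rng):
        n, m = 100, 4
        Z = rng.standard_normal((n, m))
        y = Z @ np.array([1.0, -0.5, 0.2, 0.0]) + rng.normal(0, 0.1, n)
        X = pd.DataFrame(Z.T, index=[f"cg{i}" for i in range(m)],
                         columns=[f"S{j}" for j in range(n)])
        ys = pd.Series(y, index=X.columns)
        coefs, sites = fit_sparse_subset(
            X, ys, alpha_grid=np.array([1e-8]), l1_ratio=0.5
        )
        Zs = (Z - Z.mean(0)) / Z.std(0, ddof=1)
        beta_ls, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(n), Zs]), y, rcond=None
        )
        for j, f in enumerate([f"cg{i}" for i in range(m)]):
            assert coefs.get(f, 0.0) == pytest.approx(beta_ls[j + 1], abs=1e-3)

    def test_infinite_penalty_gives_null_model(self, rng):
        n, m = 60, 5
        X = pd.DataFrame(rng.standard_normal((m, n)),
                         index=[f"cg{i}" for i in range(m)],
                         columns=[f"S{j}" for j in range(n)])
        ys = pd.Series(rng.standard_normal(n), index=X.columns)
        coefs, sites = fit_sparse_subset(
            X, ys, alpha_grid=np.array([1e6]), l1_ratio=0.5
        )
        assert coefs == {} and sites == []

    def test_selects_true_support(self, rng):
        n, m = 150, 30
        Z = rng.standard_normal((n, m))
        y = 1.2 * Z[:, 0] - 0.9 * Z[:, 1] + rng.normal(0, 0.3, n)
        X = pd.DataFrame(Z.T, index=[f"cg{i}" for i in range(m)],
                         columns=[f"S{j}" for j in range(n)])
        coefs, sites = fit_sparse_subset(X, pd.Series(y, index=X.columns))
        assert {"cg0", "cg1"} <= set(sites)
        assert len(sites) < m


class TestPredictAndCorrelate:
    def _model(self):
        return PredictorModel(
            feature_site_ids=["cg1", "cg2"],
            center=np.zeros(2), scale=np.ones(2),
            component_weights=np.eye(2), regression_weights=np.ones(2),
            coefficients=np.array([1.0, 0.0]), intercept=0.0, n_components=1,
        )

    def test_perfect_predictions_r_one(self):
        model = self._model()
        X = pd.DataFrame([[1.0, 2.0, 3.0], [0.0, 0.0, 0.0]],
                         index=["cg1", "cg2"], columns=["a", "b", "c"])
        y = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        _, r, p = predict_and_correlate(model, X, y)
        assert r == pytest.approx(1.0)

    def test_constant_predictions_undefined(self):
        model = self._model()
        X = pd.DataFrame([[2.0, 2.0, 2.0], [1.0, 1.0, 1.0]],
                         index=["cg1", "cg2"], columns=["a", "b", "c"])
        y = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        _, r, p = predict_and_correlate(model, X, y)
        assert np.isnan(r) and np.isnan(p)

    def test_missing_feature_rejected(self):
        model = self._model()
        X = pd.DataFrame([[1.0]], index=["cg1"], columns=["a"])
        with pytest.raises(KeyError, match="missing"):
            model.predict(X)


class TestROC:
    def test_perfect_separation(self):
        roc = roc_analysis([1, 2, 3, 10, 11, 12],
                           ["low", "low", "low", "high", "high", "high"])
        assert roc.auc == pytest.approx(1.0)
        assert roc.sensitivity == 1.0 and roc.specificity == 1.0

    def test_four_point_toys_match_pair_counting(self):
        def pair_count_auc(scores, labels):
            pos = [s for s, l in zip(scores, labels) if l == "high"]
            neg = [s for s, l in zip(scores, labels) if l == "low"]
            total = 0.0
            for sp in pos:
                for sn in neg:
                    total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
            return total / (len(pos) * len(neg))

        cases = [
            ([1, 2, 3, 4], ["low", "low", "high", "high"]),
            ([1, 3, 2, 4], ["low", "low", "high", "high"]),
            ([1, 1, 2, 2], ["low", "high", "low", "high"]),
            ([4, 3, 2, 1], ["low", "low", "high", "high"]),
        ]
        for scores, labels in cases:
            roc = roc_analysis(scores, labels)
            assert roc.auc == pytest.approx(pair_count_auc(scores, labels),
                                            abs=1e-12)

    def test_random_scores_auc_near_half(self, rng):
        n = 10_000
        scores = rng.standard_normal(n)
        labels = np.where(rng.random(n) < 0.5, "high", "low")
        roc = roc_analysis(scores, labels)
        assert 0.48 <= roc.auc <= 0.52

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.standard_normal(500)
        truth = (rng.random(500) < 0.4).astype(int)
        labels = np.where(truth == 1, "high", "low")
        roc = roc_analysis(scores, labels)
        assert roc.auc == pytest.approx(roc_auc_score(truth, scores), abs=1e-12)

    def test_curve_trapezoid_equals_auc(self, rng):
        scores = rng.integers(0, 5, 300).astype(float)  # heavy ties
        labels = np.where(rng.random(300) < 0.5, "high", "low")
        roc = roc_analysis(scores, labels)
        assert roc.auc == pytest.approx(np.trapezoid(roc.tpr, roc.fpr), abs=1e-12)
        assert (np.diff(roc.fpr) >= 0).all() and (np.diff(roc.tpr) >= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([1, 2, 3], ["high", "high", "high"])


class TestNoLeakage:
    def test_discovery_artifacts_invariant_to_validation_labels(self, small_dataset):
        """Corrupting validation severity leaves discovery-side fits identical."""
        from methsev.pipeline import analyze_cohort
        from methsev.predictor import split_cohort

        d = small_dataset
        split = split_cohort(list(d.samples.index), seed=3)
        disc = list(split.discovery_ids)
        val = list(split.validation_ids)

        def discovery_artifacts(samples):
            a = analyze_cohort(d.mvalues[disc], samples.loc[disc], d.manifest,
                               n_sv=5, run_region=False)
            pool = list(a.site_table.nsmallest(20, "p")["site_id"])
            model = fit_latent_regression(
                d.mvalues.loc[pool, disc], samples.loc[disc, "severity"], k=2
            )
            return a.site_table, model

        # corrupt the validation half only
        corrupted = d.samples.copy()
        corrupted.loc[val, "severity"] = 2
        t1, m1 = discovery_artifacts(d.samples)
        t2, m2 = discovery_artifacts(corrupted)
        pd.testing.assert_frame_equal(t1, t2)
        np.testing.assert_array_equal(m1.coefficients, m2.coefficients)
        np.testing.assert_array_equal(m1.center, m2.center)
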