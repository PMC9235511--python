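"""Multivariate prediction of severity from methylation.

Discovery/cross-validation half split, feature pooling from the significant
site- and region-level results of the discovery half, latent-component
(partial least squares) regression, optional elastic-net sparse subsetting,
and validation metrics: Pearson correlation of predicted vs observed scores
and ROC analysis of the dichotomized phenotype.

Everything fitted — feature list, centering/scaling, component count,
penalty — is computed from discovery samples only; validation data meet a
frozen model.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import KFold

__all__ = [
    "CohortSplit",
    "PredictorModel",
    "ROCSummary",
    "split_cohort",
    "pool_significant_sites",
    "fit_latent_regression",
    "fit_sparse_subset",
    "predict_and_correlate",
    "roc_analysis",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CohortSplit:
    discovery_ids: tuple[str, ...]
    validation_ids: tuple[str, ...]
    seed: int


@dataclass
class PredictorModel:
    """Frozen latent-component regression model.

    Predictions depend only on the stored fields:
    ``yhat = ((x - center) / scale) @ coefficients + intercept``.
    ``component_weights`` (features x k) and ``regression_weights`` (k,)
    record the latent structure behind the collapsed coefficients.
    """

    feature_site_ids: list[str]
    center: np.ndarray
    scale: np.ndarray
    component_weights: np.ndarray
    regression_weights: np.ndarray
    coefficients: np.ndarray
    intercept: float
    n_components: int
    sparse_coefficients: dict[str, float] | None = None
    provenance: dict = field(default_factory=dict)

    def predict(self, X: pd.DataFrame) -> pd.Series:
        missing = [f for f in self.feature_site_ids if f not in X.index]
        if missing:
            raise KeyError(f"validation features missing: {missing[:5]}"
                           f"{'...' if len(missing) > 5 else ''}")
        Z = X.loc[self.feature_site_ids].to_numpy(float).T  # samples x features
        Z = (Z - self.center) / self.scale
        return pd.Series(Z @ self.coefficients + self.intercept, index=X.columns,
                         name="predicted_severity")

    def to_json(self, path) -> None:
        payload = asdict(self)
        for key in ("center", "scale", "component_weights",
                    "regression_weights", "coefficients"):
            payload[key] = np.asarray(payload[key]).tolist()
        payload["format_version"] = 1
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "PredictorModel":
        with open(path) as fh:
            payload = json.load(fh)
        payload.pop("format_version", None)
        for key in ("center", "scale", "component_weights",
                    "regression_weights", "coefficients"):
            payload[key] = np.asarray(payload[key], float)
        return cls(**payload)


@dataclass
class ROCSummary:
    auc: float
    sensitivity: float
    specificity: float
    threshold: float
    fpr: np.ndarray
    tpr: np.ndarray


def split_cohort(sample_ids, seed: int) -> CohortSplit:
    """Uniform random half split; the larger half (odd n) goes to discovery."""
    ids = list(sample_ids)
    if len(ids) < 4:
        raise ValueError("need at least 4 samples to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_disc = (len(ids) + 1) // 2
    disc = tuple(ids[i] for i in sorted(perm[:n_disc]))
    val = tuple(ids[i] for i in sorted(perm[n_disc:]))
    return CohortSplit(discovery_ids=disc, validation_ids=val, seed=seed)


def pool_significant_sites(
    site_results: pd.DataFrame,
    region_results: pd.DataFrame,
    region_definitions,
    fdr: float = 0.05,
) -> list[str]:
    """Union of FDR-significant sites and member sites of significant regions.

    Both result tables must come from the discovery half only.  Returns the
    deduplicated pool ordered by site id.
    """
    sites = set(site_results.loc[site_results["q"] < fdr, "site_id"])
    if not region_results.empty:
        sig_regions = set(
            region_results.loc[
                region_results["q"].notna() & (region_results["q"] < fdr),
                "region_id",
            ]
        )
        for reg in region_definitions:
            if reg.region_id in sig_regions:
                sites.update(reg.site_ids)
    if not sites:
        raise ValueError(
            "empty feature pool; relax the FDR threshold or check the inputs"
        )
    return sorted(sites)


# ---------------------------------------------------------------------------
# latent-component regression


def _cv_components(Z: np.ndarray, y: np.ndarray, k_max: int, seed: int = 0) -> int:
    """Pick the component count by 5-fold cross-validation on discovery."""
    kf = KFold(n_splits=5, shuffle=True, random_state=seed)
    best_k, best_mse = 1, np.inf
    for k in range(1, k_max + 1):
        errs = []
        for tr, te in kf.split(Z):
            pls = PLSRegression(n_components=k, scale=False)
            pls.fit(Z[tr], y[tr])
            pred = pls.predict(Z[te]).ravel()
            errs.append(np.mean((pred - y[te]) ** 2))
        mse = float(np.mean(errs))
        if mse < best_mse - 1e-12:
            best_mse, best_k = mse, k
    return best_k


def fit_latent_regression(
    X: pd.DataFrame,
    y: pd.Series,
    k: int | str = "auto",
    max_components: int = 10,
) -> PredictorModel:
    """Partial least squares regression on standardized features.

    ``X`` is sites x samples (discovery).  Features are centered and scaled
    on discovery statistics; constant features are dropped with a warning.
    ``k="auto"`` chooses the component count by 5-fold cross-validation,
    capped at ``max_components``.  Returns a frozen model.
    """
    feats = list(X.index)
    M = X.to_numpy(float).T  # samples x features
    yv = y.loc[X.columns].to_numpy(float)
    sd = M.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        log.warning("dropping %d constant features", (~keep).sum())
        M, sd = M[:, keep], sd[keep]
        feats = [f for f, k_ in zip(feats, keep) if k_]
    center = M.mean(axis=0)
    Z = (M - center) / sd

    k_cap = min(max_components, Z.shape[1], Z.shape[0] - 1)
    if isinstance(k, str) and k == "auto":
        n_comp = _cv_components(Z, yv, k_cap)
    else:
        n_comp = int(k)
        if n_comp < 1 or n_comp > min(Z.shape[0] - 1, Z.shape[1]):
            raise ValueError(f"k={n_comp} out of range for data {Z.shape}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        pls = PLSRegression(n_components=n_comp, scale=False)
        pls.fit(Z, yv)
    coef = np.asarray(pls.coef_).reshape(-1)  # on scaled-X, raw-y
    return PredictorModel(
        feature_site_ids=feats,
        center=center,
        scale=sd,
        component_weights=np.asarray(pls.x_rotations_),
        regression_weights=np.asarray(pls.y_loadings_).reshape(-1),
        coefficients=coef,
        intercept=float(np.asarray(pls.intercept_).reshape(-1)[0]),
        n_components=n_comp,
        provenance={"n_discovery": int(Z.shape[0])},
    )


# ---------------------------------------------------------------------------
# sparse subset


def fit_sparse_subset(
    X: pd.DataFrame,
    y: pd.Series,
    alpha_grid: np.ndarray | None = None,
    l1_ratio: float = 0.5,
    seed: int = 0,
) -> tuple[dict[str, float], list[str]]:
    """Elastic-net subset selection on discovery data.

    Cyclic coordinate descent over a geometric penalty path; the penalty is
    chosen by 5-fold cross-validation with the 1-SE rule (largest penalty
    whose CV error is within one standard error of the minimum).  Returns
    (nonzero coefficients keyed by site id, selected site list).
    """
    feats = list(X.index)
    M = X.to_numpy(float).T
    yv = y.loc[X.columns].to_numpy(float)
    sd = M.std(axis=0, ddof=1)
    keep = sd > 0
    M, sd = M[:, keep], sd[keep]
    feats = [f for f, k_ in zip(feats, keep) if k_]
    Z = (M - M.mean(axis=0)) / sd
    yc = yv - yv.mean()

    n = len(yv)
    if alpha_grid is None:
        alpha_max = np.max(np.abs(Z.T @ yc)) / (n * max(l1_ratio, 1e-3))
        alpha_grid = alpha_max * np.logspace(0, -3, 50)
    alpha_grid = np.sort(np.asarray(alpha_grid, float))[::-1]

    kf = KFold(n_splits=5, shuffle=True, random_state=seed)
    mse = np.zeros((len(alpha_grid), 5))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for f, (tr, te) in enumerate(kf.split(Z)):
            for i, a in enumerate(alpha_grid):
                en = ElasticNet(alpha=a, l1_ratio=l1_ratio, fit_intercept=True,
                                max_iter=5000)
                en.fit(Z[tr], yv[tr])
                mse[i, f] = np.mean((en.predict(Z[te]) - yv[te]) ** 2)
    mean = mse.mean(axis=1)
    sem = mse.std(axis=1, ddof=1) / np.sqrt(mse.shape[1])
    i_min = int(np.argmin(mean))
    within = np.where(mean <= mean[i_min] + sem[i_min])[0]
    i_sel = int(within[0])  # grid is descending: first = largest penalty

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        en = ElasticNet(alpha=alpha_grid[i_sel], l1_ratio=l1_ratio,
                        fit_intercept=True, max_iter=10000)
        en.fit(Z, yv)
    nz = np.flatnonzero(en.coef_)
    if nz.size == 0:
        log.warning("elastic-net path produced the null model at every penalty")
    coefs = {feats[j]: float(en.coef_[j]) for j in nz}
    return coefs, [feats[j] for j in nz]


# ---------------------------------------------------------------------------
# validation metrics


def predict_and_correlate(
    model: PredictorModel, X_validation: pd.DataFrame, y_validation: pd.Series
) -> tuple[pd.Series, float, float]:
    """Frozen-model predictions plus Pearson R and its two-sided p.

    Validation features are standardized with the *discovery* center/scale
    stored in the model.  Constant predictions make R undefined; NaN is
    returned with a warning.
    """
    pred = model.predict(X_validation)
    yv = y_validation.loc[pred.index].to_numpy(float)
    if np.std(pred.to_numpy()) == 0 or np.std(yv) == 0:
        log.warning("constant predictions or outcomes; correlation undefined")
        return pred, float("nan"), float("nan")
    r, p = stats.pearsonr(pred.to_numpy(), yv)
    return pred, float(r), float(p)


def roc_analysis(scores, labels) -> ROCSummary:
    """ROC curve, AUC and the Youden-threshold operating point.

    ``labels`` are "high"/"low" (or boolean, True = high).  AUC is the
    rank statistic with half credit for ties, which equals the trapezoidal
    area under the stored curve; sensitivity/specificity are taken at the
    threshold maximizing Youden's J (labels high when score >= threshold).
    """
    s = np.asarray(scores, float)
    lab = np.asarray([
        bool(x) if not isinstance(x, str) else x == "high" for x in labels
    ])
    n_pos, n_neg = int(lab.sum()), int((~lab).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    order = np.argsort(-s, kind="mergesort")
    s_sorted, lab_sorted = s[order], lab[order]
    # collapse tied thresholds
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tp = np.cumsum(lab_sorted)[distinct]
    fp = np.cumsum(~lab_sorted)[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    auc = float(np.trapezoid(tpr, fpr))

    j = tpr - fpr
    i_best = int(np.argmax(j[1:]) + 1)  # skip the (0,0) point
    return ROCSummary(
        auc=auc,
        sensitivity=float(tpr[i_best]),
        specificity=float(1.0 - fpr[i_best]),
        threshold=float(thresholds[i_best]),
        fpr=fpr,
        tpr=tpr,
    )
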