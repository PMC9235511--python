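"""Per-CpG association of methylation with severity.

Each site's M-values are regressed on a shared design (intercept, age, sex,
batch indicators, cell proportions, surrogate variables, severity last);
residual variances are shrunk toward a common prior by the empirical-Bayes
scaled-F moment estimator, giving moderated t-statistics with augmented
degrees of freedom.  Genomic inflation (lambda) and Benjamini-Hochberg FDR
round out the stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "ModerationParams",
    "build_design_matrix",
    "fit_site_models",
    "moderate_variances",
    "genomic_inflation",
    "adjust_fdr",
    "rank_and_annotate",
    "run_site_ewas",
]

log = logging.getLogger(__name__)

#: Median of the chi-square distribution with 1 df.
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))


@dataclass(frozen=True)
class ModerationParams:
    """Prior of the scaled-F variance model: s_i^2 ~ s0^2 * F(df_i, d0)."""

    d0: float      # prior degrees of freedom; may be inf
    s0_sq: float   # prior variance

    def __post_init__(self) -> None:
        if not self.d0 > 0:
            raise ValueError("d0 must be > 0")
        if not self.s0_sq > 0:
            raise ValueError("s0_sq must be > 0")


# ---------------------------------------------------------------------------
# design


def build_design_matrix(
    samples: pd.DataFrame,
    surrogate: pd.DataFrame | None = None,
    severity_col: str = "severity",
    drop_aliased: bool = True,
) -> pd.DataFrame:
    """Assemble the shared design: intercept, confounders, severity last.

    Continuous covariates pass through; categorical batch columns become
    drop-first indicator columns; one cell-proportion column is dropped
    because the proportions sum to one (aliased with the intercept).
    Aliased/collinear columns are removed with a warning rather than
    erroring, since small simulated cohorts produce them routinely.
    """
    if severity_col not in samples.columns:
        raise KeyError(f"sample table lacks {severity_col!r}")
    parts: list[pd.DataFrame] = [
        pd.DataFrame({"intercept": np.ones(len(samples))}, index=samples.index)
    ]
    if "age" in samples:
        parts.append(samples[["age"]].astype(float))
    if "sex" in samples:
        parts.append(samples[["sex"]].astype(float))
    for col in samples.columns:
        if col.startswith("batch"):
            d = pd.get_dummies(samples[col], prefix=col, drop_first=True, dtype=float)
            parts.append(d)
    cell_cols = [c for c in samples.columns if c.startswith("cell_")]
    if cell_cols:
        parts.append(samples[cell_cols[:-1]].astype(float))  # drop one: sum-to-1
    if surrogate is not None:
        parts.append(surrogate.loc[samples.index])
    parts.append(samples[[severity_col]].astype(float))
    X = pd.concat(parts, axis=1)

    # Drop aliased columns (keep severity): greedy QR-based rank check.
    A = X.to_numpy(float)
    keep: list[int] = []
    rank = 0
    for j in range(A.shape[1]):
        cand = A[:, keep + [j]]
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            keep.append(j)
            rank = r
    dropped = [X.columns[j] for j in range(A.shape[1]) if j not in keep]
    if dropped:
        if severity_col in dropped or not drop_aliased:
            raise ValueError(f"design rank-deficient; aliased columns: {dropped}")
        log.warning("dropping aliased design columns: %s", dropped)
        X = X.iloc[:, keep]
    if len(X) <= X.shape[1]:
        raise ValueError("need n_samples > n_columns")
    return X


# ---------------------------------------------------------------------------
# per-site OLS


def fit_site_models(mvalues: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """OLS of every site on the shared design; effect = severity column.

    Returns a DataFrame indexed by site id with columns ``beta`` (M-units
    per severity point), ``se``, ``s2`` (residual variance) and
    ``df_residual`` (n - rank(design)).
    """
    if list(design.index) != list(mvalues.columns):
        if set(design.index) != set(mvalues.columns):
            raise ValueError("design rows do not align with matrix samples")
        design = design.loc[mvalues.columns]
    X = design.to_numpy(float)
    Y = mvalues.to_numpy(float)  # sites x samples
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError("rank-deficient design; run build_design_matrix first")
    df = n - p

    Q, Rm = np.linalg.qr(X)
    B = np.linalg.solve(Rm, Q.T @ Y.T)          # p x sites
    resid = Y.T - X @ B
    rss = np.einsum("ij,ij->j", resid, resid)
    s2 = rss / df
    XtX_inv = np.linalg.inv(Rm.T @ Rm)
    c_sev = XtX_inv[-1, -1]
    se = np.sqrt(np.maximum(s2 * c_sev, 0.0))
    return pd.DataFrame(
        {
            "beta": B[-1],
            "se": se,
            "s2": s2,
            "df_residual": df,
        },
        index=mvalues.index,
    )


# ---------------------------------------------------------------------------
# empirical-Bayes moderation


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    x = np.asarray(x, float)
    y = 0.5 + 1.0 / x  # good starting value
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if np.all(np.abs(dif) < 1e-10 * y):
            break
    return y


def estimate_prior(s2: np.ndarray, df: float) -> ModerationParams:
    """Closed-form method of moments on log s^2 under the scaled-F model."""
    s2 = np.asarray(s2, float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("all residual variances degenerate")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    m = len(e)
    e_var = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if e_var > 0:
        d0 = float(2.0 * _trigamma_inverse(np.array([e_var]))[0])
        s0_sq = float(
            np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        )
    else:
        d0 = np.inf
        s0_sq = float(np.exp(e.mean()))
    return ModerationParams(d0=d0, s0_sq=s0_sq)


def moderate_variances(
    fits: pd.DataFrame, prior: ModerationParams | None = None
) -> tuple[ModerationParams, pd.DataFrame]:
    """Shrink residual variances and form moderated t-statistics.

    s2_post = (d0*s0^2 + df*s2) / (d0 + df); t_mod = beta / (se * s_post/s);
    two-sided p from Student t with df + d0 degrees of freedom.  When every
    site variance is tightly clustered the estimator returns d0 = inf and
    the statistics collapse to the pooled-variance z-test; with heavy-tailed
    variance spread d0 ~ 0 and the ordinary t-test is recovered.
    """
    if len(fits) < 10 and prior is None:
        raise ValueError("need >= 10 sites to estimate the variance prior")
    s2 = fits["s2"].to_numpy(float)
    df = float(fits["df_residual"].iloc[0])
    if prior is None:
        if np.all(s2 == 0):
            raise ValueError("all residual variances are zero")
        prior = estimate_prior(s2, df)

    if np.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0_sq)
        df_total = np.inf
    else:
        s2_post = (prior.d0 * prior.s0_sq + df * s2) / (prior.d0 + df)
        df_total = df + prior.d0

    # se scales with s, so the moderated se is se * s_post / s.
    with np.errstate(divide="ignore", invalid="ignore"):
        se_mod = fits["se"].to_numpy() * np.sqrt(
            np.where(s2 > 0, s2_post / s2, np.inf)
        )
        # For s2 == 0 sites the moderated se comes straight from the prior.
        zero = s2 == 0
        if zero.any():
            c = (fits["se"].to_numpy() ** 2)[~zero] / s2[~zero]
            c_sev = float(c[0]) if len(c) else np.nan
            se_mod[zero] = np.sqrt(c_sev * s2_post[zero])
        t_mod = fits["beta"].to_numpy() / se_mod
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    out = fits.copy()
    out["s2_post"] = s2_post
    out["t_mod"] = t_mod
    out["p"] = p
    return prior, out


# ---------------------------------------------------------------------------
# inflation, FDR, ranking


def genomic_inflation(p: np.ndarray | pd.Series) -> float:
    """Genomic inflation factor lambda.

    Transform p-values to 1-df chi-square quantiles (upper-tail convention)
    and divide the observed median by the null chi-square median 0.4549.
    """
    p = np.asarray(p, float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def adjust_fdr(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, original order restored."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def rank_and_annotate(results: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Sort by p (ties by site id), attach manifest annotation and ranks."""
    out = results.copy()
    out["q"] = adjust_fdr(out["p"])
    out = out.reset_index().rename(columns={out.index.name or "index": "site_id"})
    ann = manifest.set_index("probe_id")[["chr", "pos", "gene", "location_class"]]
    out = out.join(ann, on="site_id")
    missing = out["chr"].isna()
    if missing.any():
        log.warning("%d sites missing from manifest; annotated 'unmapped'",
                    missing.sum())
        out.loc[missing, ["chr", "gene", "location_class"]] = "unmapped"
    out = out.sort_values(["p", "site_id"], kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def run_site_ewas(
    mvalues: pd.DataFrame,
    design: pd.DataFrame,
    manifest: pd.DataFrame,
) -> tuple[pd.DataFrame, ModerationParams, float]:
    """Fit, moderate, rank: the full site-level stage.

    Returns (ranked result table, moderation prior, inflation lambda).
    """
    fits = fit_site_models(mvalues, design)
    prior, moderated = moderate_variances(fits)
    lam = genomic_inflation(moderated["p"])
    table = rank_and_annotate(moderated, manifest)
    return table, prior, lam
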