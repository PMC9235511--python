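"""Region-level association: reversed Poisson-GLM deviance test.

Rather than averaging methylation across a region, the severity score
(a small-integer count) is regressed on confounders alone (step 1) and then
on confounders plus *all* CpG sites in the region (step 2), both as Poisson
log-link GLMs.  The deviance drop between the nested fits is chi-square
distributed with degrees of freedom equal to the dimension of the added
site block, so a region's p-value measures the joint improvement in fit
normalized for the number of sites it contains.

Regions come in three strata, tested and corrected as separate families:
CpG islands (from the manifest), promoters (non-island TSS-mapped sites,
grouped per gene) and gene bodies (non-island intragenic sites per gene).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .site_ewas import adjust_fdr

__all__ = [
    "RegionDefinition",
    "GLMFit",
    "define_regions",
    "fit_poisson_glm",
    "poisson_deviance",
    "region_deviance_test",
    "region_scan",
    "adjust_region_pvalues",
]

log = logging.getLogger(__name__)

PROMOTER_CLASSES = frozenset({"TSS200", "TSS1500"})
BODY_CLASSES = frozenset({"Body", "5'UTR", "3'UTR"})


@dataclass(frozen=True)
class RegionDefinition:
    region_id: str
    region_type: str  # island | promoter | gene_body
    site_ids: tuple[str, ...]
    gene: str
    chr: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.site_ids:
            raise ValueError("region must contain at least one site")
        if self.start > self.end:
            raise ValueError("start > end")


@dataclass
class GLMFit:
    coefficients: np.ndarray
    deviance: float
    iterations: int
    converged: bool
    rank: int
    fitted: np.ndarray = field(repr=False, default=None)


def define_regions(manifest: pd.DataFrame) -> list[RegionDefinition]:
    """Partition manifest sites into island, promoter and gene-body regions.

    Island regions are keyed by the manifest island id; non-island TSS200/
    TSS1500 sites are grouped per gene as promoter regions; non-island
    Body/UTR sites per gene as gene-body regions.  Singletons are allowed.
    Non-island sites without a gene label cannot be assigned and are left
    out (their count is logged).
    """
    if manifest["pos"].isna().any():
        raise ValueError("manifest sites with missing coordinates")
    regions: list[RegionDefinition] = []

    def _mk(region_id: str, rtype: str, block: pd.DataFrame, gene: str) -> None:
        chrs = block["chr"].unique()
        if len(chrs) != 1:
            raise ValueError(f"region {region_id} spans chromosomes {list(chrs)}")
        block = block.sort_values("pos")
        regions.append(
            RegionDefinition(
                region_id=region_id,
                region_type=rtype,
                site_ids=tuple(block["probe_id"]),
                gene=gene,
                chr=str(chrs[0]),
                start=int(block["pos"].min()),
                end=int(block["pos"].max()),
            )
        )

    island = manifest[manifest["island_id"].astype(str) != ""]
    for isl, block in island.groupby("island_id", sort=True):
        gene = next((g for g in block["gene"] if g), "")
        _mk(str(isl), "island", block, gene)

    nonisland = manifest[manifest["island_id"].astype(str) == ""]
    promoter = nonisland[nonisland["location_class"].isin(PROMOTER_CLASSES)]
    body = nonisland[nonisland["location_class"].isin(BODY_CLASSES)]
    skipped = 0
    for rtype, prefix, frame in (
        ("promoter", "prom", promoter),
        ("gene_body", "body", body),
    ):
        for gene, block in frame.groupby("gene", sort=True):
            if not gene:
                skipped += len(block)
                continue
            _mk(f"{prefix}_{gene}", rtype, block, str(gene))
    if skipped:
        log.info("%d non-island sites without gene label left unassigned", skipped)
    return regions


# ---------------------------------------------------------------------------
# Poisson GLM by IRLS


def poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    """2 * sum[y log(y/mu) - (y - mu)], with y log(y/mu) = 0 at y = 0."""
    y = np.asarray(y, float)
    mu = np.asarray(mu, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def fit_poisson_glm(
    y: np.ndarray, X: np.ndarray, tol: float = 1e-8, max_iter: int = 50
) -> GLMFit:
    """Poisson log-link fit by iteratively reweighted least squares.

    Convergence when the relative deviance change drops below ``tol``;
    non-convergence is flagged, not raised, so callers can mark the region
    untested.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    if np.any(y < 0):
        raise ValueError("negative response values")
    if len(y) != X.shape[0]:
        raise ValueError("response/design row mismatch")

    mu = y + np.mean(y) / 2.0 + 0.1  # strictly positive start
    eta = np.log(mu)
    dev = poisson_deviance(y, mu)
    beta = np.zeros(X.shape[1])
    rank = 0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = np.sqrt(mu)
        z = eta + (y - mu) / mu
        beta, _, rank, _ = np.linalg.lstsq(X * w[:, None], z * w, rcond=None)
        eta = X @ beta
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        new_dev = poisson_deviance(y, mu)
        if abs(new_dev - dev) < tol * (abs(dev) + 0.1):
            dev = new_dev
            converged = True
            break
        dev = new_dev
    return GLMFit(
        coefficients=beta,
        deviance=dev,
        iterations=it,
        converged=converged,
        rank=int(rank),
        fitted=mu,
    )


def _site_block_rank(
    confounders: np.ndarray, sites: np.ndarray, rel_tol: float = 1e-10
) -> int:
    """Rank of the site block after projecting out the confounder columns."""
    Q, _ = np.linalg.qr(confounders)
    resid = sites - Q @ (Q.T @ sites)
    s = np.linalg.svd(resid, compute_uv=False)
    if s.size == 0 or s[0] == 0:
        return 0
    return int(np.sum(s > rel_tol * s[0]))


def region_deviance_test(
    severity: np.ndarray,
    confounders: np.ndarray,
    region_sites: np.ndarray,
    step1: GLMFit | None = None,
    df_guard: int = 10,
) -> dict:
    """Two-step nested Poisson deviance test for one region.

    ``region_sites`` is samples x n_sites (M-values).  chi2 =
    deviance(step 1) - deviance(step 2) >= 0 by nesting; df = rank of the
    site block orthogonal to the confounders (equals n_sites when full
    rank); p = upper chi-square tail.  Regions with more sites than
    ``n - rank(confounders) - df_guard`` are skipped.
    """
    severity = np.asarray(severity, float)
    confounders = np.asarray(confounders, float)
    region_sites = np.atleast_2d(np.asarray(region_sites, float))
    if region_sites.shape[0] != len(severity):
        region_sites = region_sites.T
    n, n_sites = region_sites.shape
    conf_rank = np.linalg.matrix_rank(confounders)
    if n_sites > n - conf_rank - df_guard:
        return {"status": "skipped", "reason": "insufficient df",
                "n_sites": n_sites}

    if step1 is None:
        step1 = fit_poisson_glm(severity, confounders)
    X2 = np.hstack([confounders, region_sites])
    step2 = fit_poisson_glm(severity, X2)
    if not (step1.converged and step2.converged):
        return {"status": "untested", "reason": "non-convergence",
                "n_sites": n_sites}

    df = _site_block_rank(confounders, region_sites)
    if df < n_sites:
        log.warning("rank-deficient site block: df reduced to %d of %d",
                    df, n_sites)
    chi2 = step1.deviance - step2.deviance
    if chi2 < -1e-6:
        raise AssertionError(f"nested deviance increased by {-chi2}")
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return {
        "status": "ok",
        "chi2": float(chi2),
        "df": int(df),
        "n_sites": int(n_sites),
        "p": p,
    }


def region_scan(
    severity: pd.Series,
    confounders: pd.DataFrame,
    mvalues: pd.DataFrame,
    regions: list[RegionDefinition],
    df_guard: int = 10,
) -> pd.DataFrame:
    """Run the deviance test over all regions; step 1 is fitted once.

    ``confounders`` must include an intercept column.  Returns a table with
    one row per region (untested/skipped regions carry NaN statistics).
    """
    y = severity.to_numpy(float)
    C = confounders.loc[severity.index].to_numpy(float)
    step1 = fit_poisson_glm(y, C)
    if not step1.converged:
        raise RuntimeError("confounder-only Poisson fit did not converge")
    mvalues = mvalues.loc[:, severity.index]
    values = mvalues.to_numpy()
    site_index = pd.Index(mvalues.index)
    rows = []
    for reg in regions:
        pos = site_index.get_indexer(list(reg.site_ids))
        present = pos >= 0
        if not present.any():
            continue
        S = values[pos[present], :].T  # samples x sites
        res = region_deviance_test(y, C, S, step1=step1, df_guard=df_guard)
        rows.append(
            {
                "region_id": reg.region_id,
                "region_type": reg.region_type,
                "gene": reg.gene,
                "chr": reg.chr,
                "start": reg.start,
                "end": reg.end,
                "n_sites": int(present.sum()),
                "df": res.get("df", np.nan),
                "chi2": res.get("chi2", np.nan),
                "p": res.get("p", np.nan),
                "status": res["status"],
            }
        )
    return pd.DataFrame(rows)


def adjust_region_pvalues(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Bonferroni and BH correction within each region-type family."""
    out = results.copy()
    out["p_bonferroni"] = np.nan
    out["q"] = np.nan
    out["sig_bonferroni"] = False
    out["sig_fdr"] = False
    for rtype, block in out.groupby("region_type"):
        tested = block.index[block["p"].notna()]
        m = len(tested)
        if m == 0:
            continue
        p = out.loc[tested, "p"].to_numpy()
        out.loc[tested, "p_bonferroni"] = np.minimum(p * m, 1.0)
        out.loc[tested, "q"] = adjust_fdr(p)
        out.loc[tested, "sig_bonferroni"] = out.loc[tested, "p_bonferroni"] < alpha
        out.loc[tested, "sig_fdr"] = out.loc[tested, "q"] < alpha
    return out
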