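"""Array preprocessing: M-values, QC filters, cell composition, surrogate variables.

Inputs are assumed already background-corrected and normalized; this module
starts from intensities or M-values.  Missing values are not supported —
matrices must be complete.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "ExclusionLists",
    "CellReference",
    "compute_m_values",
    "qc_filter_samples",
    "filter_sites",
    "estimate_cell_composition",
    "estimate_surrogate_variables",
]

log = logging.getLogger(__name__)


@dataclass
class ExclusionLists:
    """Probe blacklists applied before analysis."""

    cross_reactive: set[str] = field(default_factory=set)
    snp_overlap: set[str] = field(default_factory=set)
    sex_chromosome: set[str] = field(default_factory=set)
    smoking_associated: set[str] = field(default_factory=set)


@dataclass
class CellReference:
    """Reference methylation profiles for cell-type deconvolution.

    ``profiles``: sites x cell-types DataFrame on the same scale as the
    matrix to be decomposed.
    """

    profiles: pd.DataFrame

    def __post_init__(self) -> None:
        if self.profiles.shape[1] < 2:
            raise ValueError("need at least 2 cell types")

    @property
    def cell_types(self) -> list[str]:
        return list(self.profiles.columns)


def compute_m_values(meth: pd.DataFrame, unmeth: pd.DataFrame) -> pd.DataFrame:
    """M = log2((methylated + 1) / (unmethylated + 1)), elementwise."""
    if meth.shape != unmeth.shape:
        raise ValueError("methylated/unmethylated shapes differ")
    if (meth.to_numpy() < 0).any() or (unmeth.to_numpy() < 0).any():
        raise ValueError("negative intensities")
    return np.log2((meth + 1.0) / (unmeth + 1.0))


def qc_filter_samples(
    meth: pd.DataFrame, unmeth: pd.DataFrame, threshold: float = 11.0
) -> tuple[list[str], pd.DataFrame]:
    """Drop samples with low median log2 intensity in either channel.

    The threshold applies to the per-sample median of log2(intensity + 1);
    a sample is dropped iff either channel's median is strictly below it.
    Returns (retained sample ids, per-sample QC report).
    """
    if meth.empty:
        raise ValueError("empty intensity matrix")
    med_m = np.log2(meth + 1.0).median(axis=0)
    med_u = np.log2(unmeth + 1.0).median(axis=0)
    report = pd.DataFrame(
        {"median_log2_meth": med_m, "median_log2_unmeth": med_u}
    )
    report["dropped"] = (med_m < threshold) | (med_u < threshold)
    retained = report.index[~report["dropped"]].tolist()
    if report["dropped"].any():
        log.info("QC dropped %d samples below %.1f", report["dropped"].sum(), threshold)
    return retained, report


def filter_sites(
    manifest: pd.DataFrame, lists: ExclusionLists
) -> tuple[list[str], dict[str, int]]:
    """Remove blacklisted and sex-chromosome probes.

    Union of the four exclusion lists plus any manifest site on chromosome
    X/Y.  Per-reason counts deduplicate in the fixed order cross-reactive ->
    SNP -> sex chromosome -> smoking: a probe on several lists is counted
    once, under the first applicable reason.  Unknown probe ids in the lists
    are ignored with a warning.
    """
    all_ids = set(manifest["probe_id"])
    sex_manifest = set(
        manifest.loc[manifest["chr"].astype(str).isin(["X", "Y"]), "probe_id"]
    )
    reasons = [
        ("cross_reactive", lists.cross_reactive),
        ("snp_overlap", lists.snp_overlap),
        ("sex_chromosome", lists.sex_chromosome | sex_manifest),
        ("smoking_associated", lists.smoking_associated),
    ]
    unknown = (
        lists.cross_reactive | lists.snp_overlap | lists.sex_chromosome
        | lists.smoking_associated
    ) - all_ids
    if unknown:
        log.warning("%d exclusion-list probe ids not in manifest; ignored", len(unknown))

    counts: dict[str, int] = {}
    removed: set[str] = set()
    for name, ids in reasons:
        new = (ids & all_ids) - removed
        counts[name] = len(new)
        removed |= new
    retained = [pid for pid in manifest["probe_id"] if pid not in removed]
    return retained, counts


def estimate_cell_composition(
    mvalues: pd.DataFrame, ref: CellReference
) -> pd.DataFrame:
    """Reference-based cell deconvolution by constrained least squares.

    For each sample, solve min ||P w - x||^2 subject to w >= 0 and
    sum(w) = 1, where P holds the reference profiles at the shared sites —
    the feasible set of the classic constrained-projection estimator.
    Returns a samples x cell-types DataFrame plus a ``residual`` column.
    """
    shared = ref.profiles.index.intersection(mvalues.index)
    k = ref.profiles.shape[1]
    if len(shared) < k:
        raise ValueError(
            f"only {len(shared)} shared reference sites for {k} cell types"
        )
    P = ref.profiles.loc[shared].to_numpy(float)
    X = mvalues.loc[shared].to_numpy(float)

    w0 = np.full(k, 1.0 / k)
    constraints = [{"type": "eq", "fun": lambda w: w.sum() - 1.0}]
    bounds = [(0.0, 1.0)] * k
    rows = []
    for j in range(X.shape[1]):
        x = X[:, j]
        res = optimize.minimize(
            lambda w: 0.5 * np.sum((P @ w - x) ** 2),
            w0,
            jac=lambda w: P.T @ (P @ w - x),
            bounds=bounds,
            constraints=constraints,
            method="SLSQP",
            options={"maxiter": 200, "ftol": 1e-14},
        )
        w = np.clip(res.x, 0.0, None)
        w /= w.sum()
        rows.append(np.concatenate([w, [np.linalg.norm(P @ w - x)]]))
    return pd.DataFrame(
        rows, index=mvalues.columns, columns=ref.cell_types + ["residual"]
    )


def estimate_surrogate_variables(
    mvalues: pd.DataFrame,
    severity: pd.Series,
    confounders: pd.DataFrame,
    k: int = 10,
    return_singular_values: bool = False,
):
    """Surrogate variables from the residual latent subspace.

    Two steps.  (1) Residualize the site x sample matrix on severity plus
    the known confounders and take the top ``k`` *left* singular vectors of
    the residual — the site-loading basis of the unmeasured structure,
    estimated with the phenotype of interest protected.  (2) Project the
    *original* matrix onto that basis to obtain per-sample surrogate
    scores.  The second step is what keeps downstream tests calibrated: a
    latent factor that is correlated with severity by chance must re-enter
    the design with that component intact, otherwise adjusting for it
    removes residual variance while leaving the confounded part of the
    effect in place.  Scores are centered and orthonormalized (QR).
    """
    n = mvalues.shape[1]
    design = np.column_stack(
        [np.ones(n), severity.to_numpy(float), confounders.to_numpy(float)]
    )
    rank = np.linalg.matrix_rank(design)
    if k >= n - rank:
        raise ValueError(f"k={k} too large for n={n}, design rank {rank}")
    Y = mvalues.to_numpy(float)
    beta, *_ = np.linalg.lstsq(design, Y.T, rcond=None)
    R = Y - (design @ beta).T
    U, s, _ = np.linalg.svd(R, full_matrices=False)
    basis = U[:, :k]  # sites x k loading directions
    scores = Y.T @ basis  # samples x k, from the original matrix
    scores -= scores.mean(axis=0)
    Q, _ = np.linalg.qr(scores)
    sv = pd.DataFrame(
        Q[:, :k], index=mvalues.columns, columns=[f"SV{i + 1}" for i in range(k)]
    )
    if return_singular_values:
        return sv, s[:k]
    return sv
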