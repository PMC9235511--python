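"""End-to-end orchestration: preprocess -> severity -> site EWAS -> region
EWAS -> enrichment -> predictor, with per-stage outputs and a run manifest.

Each stage writes its table under the output directory; the exact config
and seeds that produced a run are serialized next to the outputs so any
directory is self-describing and reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .enrichment import (
    GWAS_SNP_WINDOWS,
    LINKAGE_WINDOWS,
    fisher_enrichment,
    map_sites_to_genes,
    window_enrichment,
)
from .io import (
    PipelineConfig,
    read_bed_windows,
    read_exclusion_lists,
    read_gmt,
    read_manifest,
    read_methylation_matrix,
    read_sample_table,
    write_regions_bed,
    write_sites_bed,
)
from .predictor import (
    fit_latent_regression,
    fit_sparse_subset,
    pool_significant_sites,
    predict_and_correlate,
    roc_analysis,
    split_cohort,
)
from .preprocess import (
    CellReference,
    compute_m_values,
    estimate_cell_composition,
    estimate_surrogate_variables,
    filter_sites,
    qc_filter_samples,
)
from .region_ewas import adjust_region_pvalues, define_regions, region_scan
from .severity import dichotomize_severity, score_table
from .simulate import SimConfig, simulate_dataset
from .site_ewas import build_design_matrix, run_site_ewas

__all__ = ["run_pipeline", "analyze_cohort", "CohortAnalysis"]

log = logging.getLogger(__name__)


@dataclass
class CohortAnalysis:
    """Site- and region-level results for one set of samples."""

    design: pd.DataFrame
    site_table: pd.DataFrame
    lambda_inflation: float
    region_table: pd.DataFrame
    regions: list


def analyze_cohort(
    mvalues: pd.DataFrame,
    samples: pd.DataFrame,
    manifest: pd.DataFrame,
    n_sv: int = 10,
    fdr: float = 0.05,
    df_guard: int = 10,
    run_region: bool = True,
) -> CohortAnalysis:
    """Site + region association for the given samples.

    Surrogate variables are estimated from these samples only, so calling
    this on a discovery half leaks nothing from the validation half.
    """
    confounder_cols = [
        c for c in samples.columns
        if c == "age" or c == "sex" or c.startswith("batch") or c.startswith("cell_")
    ]
    conf_numeric = pd.get_dummies(
        samples[confounder_cols], drop_first=True, dtype=float
    )
    surrogate = None
    if n_sv > 0:
        surrogate = estimate_surrogate_variables(
            mvalues, samples["severity"], conf_numeric, k=n_sv
        )
    design = build_design_matrix(samples, surrogate=surrogate)
    site_table, _, lam = run_site_ewas(mvalues, design, manifest)

    regions: list = []
    region_table = pd.DataFrame()
    if run_region:
        regions = define_regions(manifest[manifest["probe_id"].isin(mvalues.index)])
        confounders = design.drop(columns=["severity"])
        raw = region_scan(samples["severity"], confounders, mvalues, regions,
                          df_guard=df_guard)
        region_table = adjust_region_pvalues(raw, alpha=fdr)
    return CohortAnalysis(design, site_table, lam, region_table, regions)


def _load_inputs(config: PipelineConfig):
    """Load user inputs, or simulate a cohort when none are given."""
    if config.mvalues is None and config.intensities_meth is None:
        sim = SimConfig(
            n_samples=config.sim_n_samples,
            n_sites=config.sim_n_sites,
            n_islands=max(config.sim_n_sites // 13, 1),
            n_genes=max(config.sim_n_sites // 3, 10),
            frac_causal_sites=config.sim_frac_causal,
            seed=config.seed,
        )
        data = simulate_dataset(sim)
        return data.manifest, data.samples, data.mvalues, None, data
    manifest = read_manifest(config.manifest)
    samples = read_sample_table(config.samples)
    intensities = None
    if config.intensities_meth is not None:
        meth = read_methylation_matrix(config.intensities_meth)
        unmeth = read_methylation_matrix(config.intensities_unmeth)
        intensities = (meth, unmeth)
        mvalues = None
    else:
        mvalues = read_methylation_matrix(config.mvalues)
    return manifest, samples, mvalues, intensities, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the summary dict.

    Outputs written under ``config.out_dir``: per-stage TSVs, BED exports,
    ``run_manifest.json`` (version, config hash, seeds) and
    ``summary.json`` (counts at thresholds, lambda, predictor metrics).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    summary: dict = {"stages": []}

    manifest, samples, mvalues, intensities, simdata = _load_inputs(config)

    # --- preprocess -------------------------------------------------------
    if intensities is not None:
        meth, unmeth = intensities
        retained, qc_report = qc_filter_samples(meth, unmeth, config.qc_threshold)
        qc_report.to_csv(out / "sample_qc.tsv", sep="\t")
        mvalues = compute_m_values(meth[retained], unmeth[retained])
        samples = samples.loc[retained]
        summary["n_samples_qc_dropped"] = int(len(meth.columns) - len(retained))
    lists = (
        read_exclusion_lists(config.exclude_dir)
        if config.exclude_dir
        else None
    )
    if lists is not None or (manifest["chr"].isin(["X", "Y"])).any():
        from .preprocess import ExclusionLists

        retained_sites, removal_counts = filter_sites(
            manifest, lists or ExclusionLists()
        )
        manifest = manifest[manifest["probe_id"].isin(retained_sites)]
        mvalues = mvalues.loc[mvalues.index.intersection(retained_sites)]
        summary["site_removal_counts"] = removal_counts
    log.info("analysis set: %d sites x %d samples", *mvalues.shape)
    summary["n_sites"] = int(mvalues.shape[0])
    summary["n_samples"] = int(mvalues.shape[1])
    summary["stages"].append("preprocess")

    # --- severity ---------------------------------------------------------
    if "severity" not in samples.columns:
        if config.clinical is None and simdata is None:
            raise ValueError("no severity scores and no clinical features given")
        clinical = read_sample_table(config.clinical)
        samples = samples.assign(severity=score_table(clinical))
    labels, thr = dichotomize_severity(
        samples["severity"], config.dichotomize_threshold
    )
    samples.assign(severity_group=labels).to_csv(out / "samples.tsv", sep="\t")
    summary["severity_mean"] = float(samples["severity"].mean())
    summary["severity_median_threshold"] = thr
    summary["stages"].append("severity")

    # --- cell composition -------------------------------------------------
    if config.cell_reference is not None:
        ref = CellReference(pd.read_csv(config.cell_reference, index_col=0))
        props = estimate_cell_composition(mvalues, ref)
        props.to_csv(out / "cell_composition.tsv", sep="\t")
        for ct in ref.cell_types:
            samples[f"cell_{ct}"] = props[ct]

    # --- site + region EWAS ----------------------------------------------
    analysis = analyze_cohort(
        mvalues, samples, manifest,
        n_sv=config.n_sv, fdr=config.fdr, df_guard=config.df_guard,
        run_region=config.run_region,
    )
    site_table = analysis.site_table
    if config.run_site:
        site_table.to_csv(out / "site_results.tsv", sep="\t", index=False)
        sig_sites = site_table[site_table["q"] < config.fdr]
        write_sites_bed(sig_sites, out / "significant_sites.bed")
        summary["lambda"] = round(analysis.lambda_inflation, 2)
        summary["n_sites_fdr_significant"] = int(len(sig_sites))
        summary["stages"].append("site_ewas")
    region_table = analysis.region_table
    if config.run_region and not region_table.empty:
        region_table.to_csv(out / "region_results.tsv", sep="\t", index=False)
        sig_regions = region_table[region_table["sig_bonferroni"]]
        write_regions_bed(sig_regions, out / "significant_regions.bed")
        summary["n_regions_tested"] = int(region_table["p"].notna().sum())
        summary["n_regions_bonferroni"] = int(region_table["sig_bonferroni"].sum())
        summary["n_regions_fdr"] = int(region_table["sig_fdr"].sum())
        summary["stages"].append("region_ewas")

    # --- enrichment -------------------------------------------------------
    if config.run_enrichment:
        if not config.run_site:
            raise RuntimeError("enrichment needs site results; enable run_site")
        sig_ids = site_table.loc[site_table["q"] < config.fdr, "site_id"]
        sig_genes, _ = map_sites_to_genes(sig_ids, manifest)
        universe, _ = map_sites_to_genes(manifest["probe_id"], manifest)
        if config.gene_sets:
            sets = read_gmt(config.gene_sets)
            gene_enr = fisher_enrichment(sig_genes, sets, universe)
            gene_enr.to_csv(out / "gene_set_enrichment.tsv", sep="\t", index=False)
            summary["n_gene_sets_tested"] = int(len(gene_enr))
        windows = (
            read_bed_windows(config.windows)
            if config.windows
            else list(LINKAGE_WINDOWS) + list(GWAS_SNP_WINDOWS)
        )
        win_enr = window_enrichment(
            set(sig_ids), list(mvalues.index), windows, manifest
        )
        win_enr.to_csv(out / "window_enrichment.tsv", sep="\t", index=False)
        summary["stages"].append("enrichment")

    # --- predictor --------------------------------------------------------
    if config.run_predictor:
        if not (config.run_site and config.run_region):
            raise RuntimeError(
                "predictor needs site and region stages; enable run_site/run_region"
            )
        pred_summary = _run_predictor_stage(
            mvalues, samples, manifest, config, out, thr
        )
        summary.update(pred_summary)
        summary["stages"].append("predictor")

    # --- plots ------------------------------------------------------------
    if config.make_plots and config.run_site:
        from .plots import manhattan_plot, qq_plot

        manhattan_plot(site_table, fdr=config.fdr, path=out / "manhattan.png")
        qq_plot(site_table["p"], lam=analysis.lambda_inflation,
                path=out / "qq.png")

    # --- provenance -------------------------------------------------------
    run_manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "split_seed": config.split_seed,
        "config": dataclasses.asdict(config),
    }
    (out / "run_manifest.json").write_text(json.dumps(run_manifest, indent=1))
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary


def _run_predictor_stage(
    mvalues: pd.DataFrame,
    samples: pd.DataFrame,
    manifest: pd.DataFrame,
    config: PipelineConfig,
    out: Path,
    dichot_threshold: float,
) -> dict:
    """Discovery/validation split, feature pooling, PLS + elastic net."""
    split = split_cohort(list(samples.index), config.split_seed)
    disc, val = list(split.discovery_ids), list(split.validation_ids)

    disc_analysis = analyze_cohort(
        mvalues[disc], samples.loc[disc], manifest,
        n_sv=min(config.n_sv, max(len(disc) - 30, 0)),
        fdr=config.fdr, df_guard=config.df_guard,
    )
    pool = pool_significant_sites(
        disc_analysis.site_table, disc_analysis.region_table,
        disc_analysis.regions, fdr=config.fdr,
    )
    model = fit_latent_regression(
        mvalues.loc[pool, disc], samples.loc[disc, "severity"]
    )
    sparse_coefs, sparse_sites = fit_sparse_subset(
        mvalues.loc[pool, disc], samples.loc[disc, "severity"],
        seed=config.split_seed,
    )
    model.sparse_coefficients = sparse_coefs
    model.provenance.update(
        {"split_seed": config.split_seed, "fdr": config.fdr, "n_pool": len(pool)}
    )
    model.to_json(out / "predictor_model.json")

    pred, r, p = predict_and_correlate(
        model, mvalues.loc[model.feature_site_ids, val],
        samples.loc[val, "severity"],
    )
    pred.to_frame().to_csv(out / "predictions.tsv", sep="\t")
    labels = np.where(samples.loc[val, "severity"] >= dichot_threshold,
                      "high", "low")
    roc = roc_analysis(pred.to_numpy(), labels)
    pd.DataFrame({"fpr": roc.fpr, "tpr": roc.tpr}).to_csv(
        out / "roc_points.tsv", sep="\t", index=False
    )
    return {
        "n_pooled_features": len(pool),
        "n_sparse_sites": len(sparse_sites),
        "validation_R": round(r, 3),
        "validation_R_pvalue": p,
        "validation_auc": round(roc.auc, 3),
        "validation_sensitivity": round(roc.sensitivity, 3),
        "validation_specificity": round(roc.specificity, 3),
    }
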