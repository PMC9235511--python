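"""Per-CpG severity EWAS with empirical-Bayes variance moderation.

Fits M ~ intercept + age + sex + batches + cell proportions + 10 surrogate
variables + severity for every site, shrinks residual variances toward a
common prior, and reports moderated-t p-values with BH-FDR control and the
genomic inflation factor lambda.
"""

from methsev import SimConfig, simulate_dataset
from methsev.pipeline import analyze_cohort

data = simulate_dataset(SimConfig(n_samples=232, n_sites=4000, n_islands=300,
                                  n_genes=1300, seed=42))
res = analyze_cohort(data.mvalues, data.samples, data.manifest, n_sv=10,
                     run_region=False)

top = res.site_table.head(5)[["site_id", "chr", "pos", "beta", "p", "q",
                              "gene", "rank"]]
print(top.to_string(index=False))
n_sig = int((res.site_table["q"] < 0.05).sum())
n_causal_found = len(
    set(res.site_table.loc[res.site_table["q"] < 0.05, "site_id"])
    & set(data.truth.causal_site_ids)
)
print(f"\nlambda = {res.lambda_inflation:.2f} "
      "(~1 means the test is calibrated after confounder adjustment)")
print(f"{n_sig} FDR-significant sites, {n_causal_found} of them truly causal "
      f"of {len(data.truth.causal_site_ids)} planted")
print("-> beta is the M-value change per severity point at that CpG.")
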