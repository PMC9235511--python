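"""Region-level test: reversed Poisson-GLM deviance over islands/promoters.

For each region the severity count is regressed on confounders alone and
then on confounders plus all the region's CpGs; the deviance drop is
chi-square with df = number of (independent) added sites, measuring the
joint improvement normalized for region size.
"""

from methsev import SimConfig, simulate_dataset
from methsev.pipeline import analyze_cohort

data = simulate_dataset(SimConfig(n_samples=232, n_sites=4000, n_islands=300,
                                  n_genes=1300, seed=42))
res = analyze_cohort(data.mvalues, data.samples, data.manifest, n_sv=10)

table = res.region_table.sort_values("p")
cols = ["region_id", "region_type", "gene", "n_sites", "chi2", "df", "p",
        "p_bonferroni"]
print(table.head(5)[cols].to_string(index=False))
n_bonf = int(table["sig_bonferroni"].sum())
hits = set(table.loc[table["sig_bonferroni"], "region_id"])
print(f"\n{n_bonf} Bonferroni-significant regions "
      f"(families: islands, promoters, gene bodies corrected separately)")
print(f"planted causal islands recovered: "
      f"{sorted(set(data.truth.causal_region_ids) & hits)}")
print("-> a significant region means its CpGs jointly explain severity "
      "beyond the confounders.")
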