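"""Select tumor-overexpressed signature genes and the prognostically optimal
signature size, then classify patients by their NBT score.

Pipeline: pooled TMM/log-CPM normalization -> paired moderated-t DEG testing
-> filters (log2FC > 1, FDR < 0.05, avg log2CPM > 3) -> fold-change ranking
-> ssGSEA scoring of NBTs on the top-k genes for k = 10..50 -> per-k
mean-score split and Cox fit -> k with the highest hazard ratio wins.
"""

from nbtsig import SimulationConfig, simulate_cohort
from nbtsig.pipeline import analyze_cohort

cohort = simulate_cohort(SimulationConfig(n_patients=120, n_genes=1000,
                                          n_signature=20, seed=2))
ranked, deg_table, sweep = analyze_cohort(
    cohort.tumor_counts, cohort.nbt_counts, cohort.clinical
)

print(f"{len(ranked)} genes pass the DEG filters")
print(sweep.table[["k", "hr", "p", "n_tsm", "n_hm"]].head(8).round(3)
      .to_string(index=False))
print(f"selected signature size: k = {sweep.selected_k} "
      f"(highest HR, ties -> fewest genes)")
print(f"cohort-mean score cutoff: {sweep.cutoff:.1f}")
hr = sweep.cox.hazard_ratio("tsm")
lo, hi = sweep.cox.summary.loc["tsm", ["ci_low", "ci_high"]]
print(f"TSM vs HM hazard ratio: {hr:.2f} (95% CI {lo:.2f}-{hi:.2f})")

truth = cohort.truth
labels = sweep.classification.labels  # indexed by patient id
agree = (labels.reindex(truth.labels.index) == truth.labels).mean()
print(f"agreement with latent truth: {agree:.1%}")
# A hazard ratio well above 1 with a high truth agreement means the NBT
# signature score has recovered the planted tumor-supportive subgroup.
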