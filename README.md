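# nbtsig

Prognostic classification of cancer cohorts by how much the *normal* tissue
margin resembles the tumor.

Given paired tumor and normal-margin (NBT, non-tumor-bearing tissue) bulk
RNA-seq count matrices and a clinical table, `nbtsig`:

1. finds tumor-overexpressed genes with a paired moderated test on
   TMM-normalized log2-CPM, filtered at `log2FC > 1`, `FDR < 0.05`,
   `avg log2CPM > 3` and ranked by fold change;
2. scores each patient's **NBT** on the top-k genes by single-sample GSEA
   (rank-weighted running sum, weight `ρ^0.25`, raw scores);
3. sweeps k = 10..50 and keeps the signature size whose cohort-mean-score
   split gives the highest Cox hazard ratio (ties → fewest genes);
4. calls patients **TSM** (tumor-supportive microenvironment) when their NBT
   score exceeds the cohort mean, else **HM** (healthy microenvironment);
5. quantifies the consequences: Kaplan–Meier / log-rank / univariate-screen
   → multivariate Cox survival analysis, and — when genus-level microbiome
   tables are available — Bray–Curtis PERMANOVA, PCoA, Berger–Parker
   dominance and paired Wilcoxon tests comparing each patient's NBT with the
   paired tumor.

A synthetic-cohort generator with planted ground truth (overexpressed gene
set, latent TSM labels with an NBT expression "leak", proportional-hazards
survival, Dirichlet-multinomial paired microbiomes) makes the whole pipeline
testable end to end; see `docs/methods.md` for the models and defaults.

## Worked example

```python
from nbtsig import SimulationConfig, simulate_cohort
from nbtsig.pipeline import analyze_cohort

cohort = simulate_cohort(SimulationConfig(n_patients=120, n_genes=1000,
                                          n_signature=20, seed=2))
ranked, deg_table, sweep = analyze_cohort(
    cohort.tumor_counts, cohort.nbt_counts, cohort.clinical)

print(len(ranked))                    # genes passing the DEG filters
print(sweep.selected_k, sweep.cutoff) # chosen signature size, mean-score cutoff
print(sweep.cox.summary.loc["tsm"])   # TSM-vs-HM Cox fit on RFS
```

Running `python examples/02_signature_sweep.py` (the same analysis) prints:

```
20 genes pass the DEG filters
...
selected signature size: k = 10 (highest HR, ties -> fewest genes)
cohort-mean score cutoff: 123.0
TSM vs HM hazard ratio: 2.07 (95% CI 1.33-3.23)
agreement with latent truth: 100.0%
```

All 20 filter-passing genes are planted ones; the NBT score split recovers
the latent TSM subgroup exactly, and the estimated hazard ratio 2.07 agrees
with the planted true hazard ratio of 2.3 within its confidence interval.
The other scripts in `examples/` walk through cohort simulation, the
survival workflow and the microbiome resemblance statistics, each printing
the numbers it computes and what they mean.

A thin CLI mirrors the stages (`nbtsig simulate | deg | signature |
classify | survival | microbiome | run`); `nbtsig run --config cfg.yaml`
executes everything and writes stage TSVs plus a manifest with checksums
(re-runs with the same seed are byte-identical). Exit codes: 0 ok, 2 config
error, 3 data error, 4 numerical failure.

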