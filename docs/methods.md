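# Methods

`nbtsig` implements a microenvironment-based prognostic classification of
paired tumor / normal-margin (NBT, non-tumor-bearing tissue) cohorts, built
around the idea that an NBT transcriptome resembling the paired tumor marks a
tumor-supportive microenvironment (TSM) with worse outcome than a healthy
microenvironment (HM). This note records the models, the defaults and why,
the numerical choices, and what the synthetic benchmark does and does not
show.

## The classification procedure

1. **Normalization.** Tumor and NBT libraries are pooled into one count
   matrix and normalized by TMM (trimmed mean of M-values): for sample *j*
   against a reference *r* (the sample whose upper-quartile CPM is closest to
   the cohort mean upper-quartile), per-gene log ratios
   `M_g = log2((y_gj/N_j)/(y_gr/N_r))` are doubly trimmed — 30% on the M
   tails, 5% on the A (average log-abundance) tails — and averaged with
   inverse asymptotic-variance weights; `f_j = 2^mean`. Factors are rescaled
   to geometric mean 1. Expression enters all downstream stages as log2-CPM
   over effective library sizes `N_j f_j` with a library-size-scaled prior
   count (default 2).

2. **Differential expression.** Per gene, a moderated paired t on the
   within-patient tumor−NBT log-CPM differences. Gene variances are shrunk by
   empirical Bayes under the scaled-F model `s_g² ~ s0² · F(n−1, d0)`; `(d0,
   s0²)` are fit by method of moments on `log s_g²` (digamma/trigamma
   identities, trigamma inverted by Newton), giving posterior variances
   `(d0·s0² + (n−1)s_g²)/(d0+n−1)` and a t reference with `d0+n−1` df. The
   original analysis this reproduces used negative-binomial quasi-likelihood
   GLMs; the paired moderated t keeps the same structure (paired contrast,
   variance moderation, BH adjustment, identical thresholds) on normalized
   log expression, which is what the synthetic truth-recovery benchmark
   exercises. This substitution is deliberate and is the package's main
   methodological simplification.

3. **Filters and ranking.** A gene is a signature candidate iff
   `log2FC > 1` (strict), BH-adjusted `FDR < 0.05` and average
   `log2CPM > 3` over all pooled samples. Candidates are ranked by fold
   change descending; ties broken by smaller p, then gene id (the ranking
   must be total for reproducibility).

4. **ssGSEA scoring.** For each sample, genes are traversed in descending
   expression order and the enrichment score is
   `ES = Σ_i (P_in(i) − P_out(i))`, where `P_in` is the weighted in-set ECDF
   with weights `ρ^α` (ρ = ascending-expression rank, α = 0.25 by default)
   and `P_out` the uniform ECDF over non-set genes. Scores are reported raw
   (unnormalized) by default — the consequential setting, since the cohort
   mean of raw scores is the classification cutoff; optional normalization
   divides by the cohort score range. Scores depend only on within-sample
   ranks; ties are broken by stable input gene order.

5. **Signature-size sweep.** For each k in 10..50 the NBT samples are scored
   on the top-k ranked genes, split at the per-k cohort-mean score
   (`score > mean → TSM`), and a single-covariate Cox model of the endpoint
   (RFS by default) is fit to the TSM indicator. The selected k attains the
   highest hazard ratio; exact ties go to the fewest genes. Selection by
   smallest p-value is available (`objective="p"`) because "most
   discriminating" can also be read that way; highest HR is the default.
   k values with a degenerate split or failed fit are recorded and skipped.

6. **Survival.** Kaplan–Meier with Greenwood errors; K-sample log-rank with
   hypergeometric variance; Cox proportional hazards by Newton–Raphson on
   the Efron-tie-corrected log partial likelihood (Breslow available), with
   step-halving, convergence at `max|score| < 1e-9` or `|Δloglik| < 1e-9`
   within 50 iterations, standard errors from the inverse observed
   information, Wald 95% CIs. Divergent coefficients (|β| > 10; monotone
   likelihood / separation) are flagged rather than silently reported.
   The prognostic-factor workflow screens candidate covariates univariately
   at Wald p < 0.1 and fits qualifiers jointly. Five-year survival is the KM
   step function at t = 60 months. At tied times events precede censorings.

7. **Microbiome resemblance.** On genus count tables: relative abundance
   (per-sample proportions), Bray–Curtis dissimilarity
   `1 − 2Σmin/(Σ+Σ)` on proportions (raw-count profiles are also accepted),
   PCoA by classical scaling (positive eigenvalues only; proportion
   explained against the positive-eigenvalue total), and PERMANOVA with the
   distance-based pseudo-F. The permutation p-value uses the add-one
   convention with a mandatory seed; when the number of distinct label
   arrangements does not exceed the requested permutation count, the null is
   enumerated exhaustively and the p-value is exact. Berger–Parker dominance
   `d = n_max/N` is emitted together with its reciprocal: d is a dominance
   (inverse-evenness) measure, and publishing both avoids hard-coding a
   directional "diversity" reading. Paired NBT-vs-tumor Wilcoxon signed-rank
   tests (zeros dropped; exact null for ≤ 25 nonzero pairs, normal
   approximation with continuity correction above; all-zero differences give
   p = 1 with a flag) are BH-adjusted across genera.

## The synthetic cohort

The generator emulates the structure of a paired resection cohort so that
every stage has a recoverable planted truth. Defaults (one place, chosen
once):

| parameter | default | meaning |
|---|---|---|
| `n_patients` | 300 | paired tumor + NBT samples per patient |
| `n_genes` | 2000 | genes in the expression matrices |
| `n_signature` | 25 | planted tumor-overexpressed genes |
| `tsm_fraction` π | 0.388 | latent TSM prevalence (38.8% of patients) |
| `tumor_log2_effect` Δ | U(2, 4) | per-planted-gene tumor log2 effect |
| `nbt_leak` δ | 0.6 | TSM NBTs express planted genes at `2^(δΔ)` |
| `dispersion` φ | 0.1 | NB dispersion, `var = μ + φμ²` |
| `lib_size_range` | 0.5–2 × 10⁶ | uniform library sizes (exercises TMM) |
| `baseline_hazard` λ0 | 0.01 /month | exponential RFS baseline (OS: 0.7·λ0) |
| `log_hazard_tsm` β | ln 2.3 | true TSM log hazard ratio |
| `censor_rate` | 0.35 | marginal censoring probability |
| `n_genera` | 60 | genera in the microbiome tables |
| `dm_concentration` θ | 25 | Dirichlet concentration around base communities |
| `dm_concentration_paired` | 300 | TSM NBT concentration around the paired tumor |
| `seq_depth` | 10⁴ | multinomial reads per 16S sample |

Counts are gamma–Poisson (negative binomial) around
`lib_size × q_g × effect` with log-normal baseline abundances `q_g`.
Survival is exponential with hazard `λ0·e^{β·1[TSM]}` and independent
exponential censoring whose rate is tuned to the marginal censoring
probability; hazard depends on the latent label only (the simplest
proportional-hazards mechanism — the dependence structure between leak
strength and hazard is unknown, so none is invented). Microbiome: tumors
scatter around an uneven base community (few dominant genera), TSM NBTs are
drawn tightly around their paired tumor composition
(`Dirichlet(θ_high · tumor)`, mean-preserving, so the groups differ in
resemblance rather than centroid), HM NBTs come from a distinct, more even
base. One global seed expands into per-component substreams
(labels/expression/survival/microbiome), so any component can be
re-simulated independently and all outputs are bit-reproducible.

The prevalence, effect ranges, leak, hazard ratio and censoring defaults are
the study conditions of a stage II–III colorectal cohort of this design;
dispersion, library sizes and the Dirichlet-multinomial settings are typical
of bulk RNA-seq and V3–V4 16S data at these depths.

**What the generator does not emulate:** read-level data, batch or center
effects, tumor purity, gene–gene correlation beyond the shared planted
signal, covariate-dependent hazards or informative censoring, and microbiome
contamination/compositional artifacts. Passing the synthetic benchmarks
therefore shows the *procedure* is correct and recovers a planted signal of
realistic size — not that the biological signature itself generalizes.

## Numerical and design notes

- **Degenerate sweeps.** With a strong NBT leak the classification can be
  identical at every k; all hazard ratios then tie exactly and the
  fewest-genes rule selects the smallest k. The selected set is in that case
  a subset of the planted genes rather than the full set — a consequence of
  the tie-break, reported as-is (the sweep table records every k).
- **BH re-application.** Adjusted p-values are not a fixed point of the full
  adjustment (re-adjusting multiplies by m/rank again); they are a fixed
  point of the step-up enforcement (running minimum from the top, cap at 1).
  Tests assert the latter.
- **TMM and library scaling.** Scaling one library leaves CPM only
  approximately unchanged: the inverse-asymptotic-variance weights depend on
  depth. A pure depth difference between two otherwise identical samples
  yields exactly unit factors (all M ≡ 0).
- **Score test vs log-rank.** The Cox score test at β = 0 with Breslow ties
  equals the two-group log-rank χ² exactly for untied event times; with ties
  the log-rank variance carries the hypergeometric `(n−d)/(n−1)` factor.
- **Problem sizes.** The test suite and the acceptance script run the full
  procedure at the default cohort size (300 patients × 2000 genes); repeated
  operating-characteristic checks (null sweeps, coverage, type-I error) use
  50–1000 replicates at these or smaller sizes, enough for the stated
  Monte-Carlo margins.
- **External validation path.** `classify` accepts a fixed numeric cutoff so
  a signature and cutoff learned on one cohort can be applied unchanged to
  another.

## Known limitations

- The moderated paired t is not an NB GLM; very low counts are handled via
  the log-CPM prior count rather than a count likelihood.
- The Cox implementation covers time-fixed covariates only (no strata,
  time-varying effects, or robust variance).
- PERMANOVA assumes exchangeability under the null; no strata/blocking.
- GSVA-style alternatives to ssGSEA (gsva, plage, z-score) are out of scope,
  as are leave-one-out or cross-validated signature selection.
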