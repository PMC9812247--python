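# braintx

Imaging transcriptomics: spatial association of brain-wide gene-expression
maps with task-fMRI activation maps, with inference corrected for spatial
autocorrelation.

## The problem

Given one expression map per gene (summarized to a parcellation of cortex
and subcortex) and an activation statistic map from a task contrast, which
genes' expression topography tracks the activation topography — and which
gene categories and transcriptional regulators do those genes point to?
The statistical difficulty is that brain maps are spatially smooth:
neighboring parcels are not independent samples, so naive permutation
p-values are badly anti-conservative. `braintx` implements the full
analysis chain for researchers who want to run it, test it, or stress it
on synthetic data with known ground truth:

1. **Per-gene association** — Spearman's ρ between each gene's regional
   expression profile and the activation profile, computed per compartment
   (cortex / subcortex, never mixed), yielding a ranked gene list.
2. **Spatial surrogate inference** — variogram-matched surrogate maps:
   permute a map, re-smooth it with distance-decaying kernels over each
   parcel's k nearest neighbors, and fit the mixture
   `sqrt(β)·smoothed + sqrt(α)·noise` so the surrogate's semivariogram
   γ(h) = ½·E[(v_i − v_j)²] matches the empirical one. Two-sided p-values
   are the literal proportion of surrogates with |ρ_surr| > |ρ_obs|
   (defaults: 1000 surrogates, k = 20 cortex / 5 subcortex).
3. **RRHO** — rank–rank hypergeometric overlap between two ranked lists:
   a map of signed −log₁₀ hypergeometric tail p-values over prefix-rank
   cutoff pairs, plus a scalar agreement coefficient ρ_RRHO.
4. **GCEA** — gene-category enrichment: a category's statistic is the mean
   gene score over its 5–200 annotated genes, tested against an ensemble
   null that recomputes all gene correlations on surrogate activation
   maps; Benjamini–Hochberg across categories.
5. **GSEA** — weighted Kolmogorov–Smirnov running sum of a risk-gene set
   down the ranked list; ES = maximal deviation from zero; permutation p.
6. **Master regulators** — per motif, recovery AUC of the large-effect
   gene set (|ρ| > 0.5) in the motif's genome-wide ranking, z-scored
   across the database (NES); regulators with NES > 3 intersected with a
   risk-gene list and reported as `regulator (n_targets/n_possible)`.

A first-class synthetic generator (`braintx.synthetic`) builds the whole
study — parcellation, autocorrelated expression fields, an activation map
with planted gene associations, a toy ontology and a motif database with a
planted master regulator — so every stage is testable without any data
downloads.

## A worked example

```bash
python examples/01_simulate_and_correlate.py
```

```
Top 10 genes by Spearman rho with the cortical activation map:
gene_id      rho  rank
   G360 0.860534     1
   G077 0.850201     2
   G474 0.845545     3
   ...

25 genes exceed rho > 0.5 (large effect size);
100% of the 25 planted genes are among them.
```

The generator planted 25 genes whose expression shares a latent spatial
factor with the activation map; all 25 exceed the large-effect threshold
ρ > 0.5 and fill the top of the ranking. The other examples walk the rest
of the chain — `02` shows the surrogate null keeping the false-positive
rate at ~5% on null data where naive permutation rejects 12%, `03`
contrasts near-zero cross-paradigm ρ_RRHO with ~0.77 cross-atlas
agreement, `04`–`05` recover the planted category (smallest adjusted p)
and the planted regulator (NES ≈ 8.8, reported as `G307 (20/25)`), and
`06` runs everything via `run_pipeline` into a byte-reproducible results
bundle.

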