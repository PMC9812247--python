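# Methods

This note documents the models, algorithms, defaults and numerical choices
behind `braintx`, and what the synthetic studies do and do not establish.

## Data model

All analyses operate on *spatial profiles*: one value per spatial unit
(voxel or parcel) for one map, restricted to a single compartment (cortex
or subcortex). Compartments are never mixed, because broad anatomical
areas differ systematically in expression and would otherwise dominate any
correlation. Zero is the background sentinel throughout: voxels with value
0 are treated as outside the investigated area and excluded before any
averaging (maps in which 0 is a legitimate value must be offset upstream —
a documented limitation). Parcel summaries are arithmetic means of
surviving voxels; parcel locations are unweighted centroids of member
voxel coordinates in mm, and inter-parcel distance is the Euclidean
distance between centroids. Volume smoothing uses a Gaussian kernel with
σ = FWHM/(2√(2 ln 2)) per axis converted to voxels; boundaries use
nearest-edge replication, so constant maps are preserved exactly.

## Per-gene association

Spearman's ρ (Pearson correlation of mid-ranks, average ranks on ties) is
used because regional expression values are partly non-symmetric with
outliers. Genes with a constant profile within a compartment have no
defined ρ; they are excluded from the ranking and counted, rather than
being assigned ρ = 0, which would distort downstream enrichment ranks.
Tables are sorted by descending ρ with a lexicographic gene-id tie-break
so outputs are byte-reproducible. Large-effect gene sets use strict
thresholds: positive = {ρ > 0.5}, negative = {ρ < −0.5}.

## Variogram-matched surrogate maps

The null model for spatial inference is a generative surrogate: maps that
are random with respect to everything except their spatial autocorrelation
fingerprint, the empirical semivariogram γ(h) = ½·mean[(v_i − v_j)²] over
distance bins. A surrogate is built by

1. permuting the map's values across parcels,
2. smoothing the permuted map with an exponentially decaying kernel
   restricted to each parcel's k nearest neighbors (k = 20 cortex,
   5 subcortex by default), at a kernel scale chosen from a geometric grid
   of 25 candidates spanning [smallest inter-centroid distance, half the
   maximum distance],
3. mixing `sqrt(β)·smoothed + sqrt(α)·white noise` with β, α ≥ 0 fitted by
   least squares so that `β·γ_smoothed + α` best matches the empirical
   variogram (non-negativity enforced by comparing the three KKT candidate
   solutions), and
4. optionally rank-remapping the surrogate's values onto the source's
   empirical value distribution, which makes the value multiset exactly
   the source's.

**Kernel-scale selection.** Permutations are exchangeable, so the
best-fitting kernel scale is a property of the map and its geometry rather
than of the individual permutation. The scale is therefore selected once
per ensemble by fitting a pilot subset (default 10 surrogates) at every
candidate scale and keeping the scale with the smallest mean residual;
β and α are still fitted per surrogate. This reduces the cost of a
1000-gene × 1000-surrogate calibration study from hours to minutes on one
CPU; `pilot=None` restores the full per-surrogate scale search, and the
two agree closely in variogram fidelity (tested).

**Variogram fit range.** The variogram is fitted over uniform distance
bins spanning (0, 0.7·max distance]. The range matters: fitting only to
half the maximum distance leaves long-range structure unconstrained and
produced measurably conservative p-values in the package's own calibration
study (rejection 0.026 at α = 0.05), while fitting the full range
overcorrects (anticonservative). The default 0.7 was selected by that
calibration study and yields near-uniform null p-values (rejection 0.036,
deciles within ~0.03 of uniform) at the default study conditions.
`compute_variogram`, used for display and fidelity checks, keeps the
geostatistics-conventional 0.5 default.

**p-values.** Two-sided spatial p is the literal proportion of surrogates
with |ρ_surr| strictly greater than |ρ_obs|; p = 0 is formatted as
"< 1/n_surrogates". For procedures that cannot accept exact zeros
(Benjamini–Hochberg), zero proportions are replaced by 1/(2·n_nulls).
Per-gene inference surrogates the *gene* map with the activation held
fixed; GCEA instead surrogates the *activation* map once for all
categories (see below). Both directions are exposed; under the null they
are equivalent.

**Fidelity.** A single surrogate's realized variogram fluctuates about as
much as a fresh realization of the generating random field does (mean
relative deviation ≈ 0.27 for a 100-parcel exponential field), so fidelity
is judged on the ensemble-averaged variogram, which tracks the empirical
one to well under 25% mean relative deviation in the tested regimes.

## RRHO

The overlap map evaluates, for each pair of rank cutoffs (multiples of a
step, default ~N/100), the upper-tail hypergeometric probability of the
observed overlap between the two top-prefixes, signed positive when the
overlap exceeds its expectation t₁t₂/N and negative otherwise, and
−log₁₀-transformed. The scalar ρ_RRHO is defined here as the Spearman
correlation between the two lists' per-gene ρ values, with a gene-label
permutation p; the originating R package's exact scalar definition is not
published in the text we follow, so ours is documented rather than claimed
identical.

## GCEA

Gene scores are one-sided transforms of ρ (max(ρ,0), max(−ρ,0)) computed
separately for positive and negative programs, or |ρ|. A category's
statistic is the mean score of its annotated genes; only categories with
5–200 annotations inside the scored universe are tested. The null
ensemble replaces the activation map with variogram-matched surrogates and
recomputes every gene's ρ per null map — one shared ensemble for all
categories, making the cost O(n_nulls · n_genes) rather than
O(n_nulls · n_genes²) — and p_raw is the proportion of null category means
≥ the observed one. Benjamini–Hochberg is applied across tested
categories (verified against a direct step-up oracle).

## GSEA

The weighted Kolmogorov–Smirnov running sum walks the descending-ρ list:
members add |ρ|^w / Σ_set|ρ|^w (w = 1 by default; w = 0 reduces to the
classic two-sample KS statistic, tested against an ECDF oracle),
non-members subtract 1/(N − m). ES is the running sum at its maximal
absolute deviation; the sum's return to zero is asserted on every call.
Significance uses gene-label permutations preserving set size, two-sided
on |ES|, with no multiplicity adjustment since a single set is tested.

## Master regulators

Each motif in the database carries a complete, tie-free ranking of the
gene universe. For a query set, the recovery curve y(x) counts set genes
at rank ≤ x for x = 1..R with R = ⌈0.05·N⌉ (the window fraction is
config-exposed); AUC = Σy/(|set|·R). NES is the z-score of a motif's AUC
across all motifs (sample SD); motifs with NES strictly above 3 nominate
their regulator. Targets are defined as query-set genes ranked within the
AUC window of the retained motif — the simplest defensible reading of
"direct targets"; leading-edge variants differ between tool versions.
When several motifs share a regulator, the max-NES motif is reported. The
final report intersects nominated regulators with the risk list and quotes
`n_targets/n_possible`; an empty large-effect set produces an explicit "–"
cell in the compartment × direction grid.

## The synthetic study

The generator emulates exactly the structure the analysis assumes:

* **Parcellation** — the voxel grid is split along z into a subcortical
  slab and cortical remainder; parcels are Voronoi cells of randomly
  placed seed voxels per compartment (nonempty and contiguous-ish by
  construction). Defaults: 100 cortical + 30 subcortical parcels on a
  20×20×12 grid of 2 mm voxels.
* **Expression** — each gene is a zero-mean Gaussian random field over
  parcel centroids with exponential covariance exp(−d/λ). λ defaults to
  6 mm ≈ 0.15 of the grid extent, chosen to mirror the ratio of
  expression-map autocorrelation length to brain size at full scale; at a
  much larger λ/extent ratio the miniature brain has so few spatial
  degrees of freedom that any two maps correlate substantially by chance.
* **Planted signal** — planted genes (fraction 0.05 → 25 genes) load on a
  shared latent field with per-gene loadings drawn uniformly in
  [0.7, 0.9] (recorded as ground-truth mixing weights); the activation map
  is `0.9·z(planted mean) + 0.1·z(independent field) + 0.2·noise`. The
  shared factor is what makes individual planted genes recoverable at
  ρ > 0.5: averaging K independent fields would cap each gene's
  correlation near 0.9/√K regardless of effect size.
* **Annotations** — random categories with sizes in [5, 50], plus one
  category holding all planted genes with ~20% random padding; a motif
  database of uniform permutations plus one motif ranking the planted
  regulator's targets (80% of the planted genes) on top; a risk list of
  the regulator, half the planted genes and five decoys.

What the synthetic study does **not** emulate: donor structure, probe
selection, hemispheric mirroring, non-stationary or anisotropic
autocorrelation, expression-level means/dispersion (fields are unit-scale
and zero-mean), and any realistic ontology topology. Passing tests
establish that the *pipeline* recovers known signal under matched
assumptions — not that real data satisfy those assumptions.

## Problem sizes used in the test studies

* Null calibration: 1000 genes × 1000 surrogates on the 100-parcel cortex;
  surrogate rejection at α = 0.05 must land in [0.03, 0.07] while naive
  permutation on the same data exceeds 0.07 (it reaches ~0.13–0.25).
* Planted recovery: 10 seeds at the default conditions; gene, category,
  risk-set and regulator recovery each required in ≥ 9/10.
* Ranked-list overlap: the cross-paradigm and cross-atlas studies run at
  210 cortical parcels (40×40×20 grid). At 100 parcels the chance
  component of ρ_RRHO between two independent smooth maps has sampling SD
  ≈ 0.2 — rank lists inherit the maps' chance spatial overlap, amplified
  by gene-field smoothness — so "near-zero" is only a stable statement at
  higher resolution; this sensitivity is a real property of small
  parcellations, not an implementation artifact.

## Known limitations

* Zero doubles as background; legitimate zero-valued data must be offset.
* Surrogate calibration was tuned and verified for exponential-covariance
  fields on parcellation-centroid geometries; maps whose autocorrelation
  decays very differently (or geometries with many near-coincident
  centroids) may need a different fit range or lag count.
* Voxel-wise p-values are left missing by default (no spatial correction
  is defined for them here).
* ρ_RRHO is our documented reading of a scalar whose original definition
  is not public; absolute values are comparable within this package only.
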