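# Methods

## Model and procedure

`crossome` treats a multi-genotype panel measured on two omes as two
feature × sample matrices of log₂ intensities sharing a sample axis
(genotype × replicate). The analysis asks which lipids and proteins
co-vary across the panel and which genotypes drive that co-variation.

**Kendall tau-b.** Associations are rank-based: for each lipid–protein
pair, τ_b = (C − D)/√((n₀ − n₁)(n₀ − n₂)) over the samples where both
features are observed. Rank correlation captures any monotone coupling and
is insensitive to the log transform and to outlying intensities; the tie
correction matters because label-free data quantised by the search engine
produce tied ranks. Missing values are handled pairwise-complete per
feature pair — no imputation — and a pair with fewer than `min_overlap`
(default 8) complete samples, or a constant marginal, yields a missing τ.

The full matrix is computed by an exact vectorised formulation: per ome,
a (sample-pairs × features) matrix of difference signs (0 for ties or
missing), a validity indicator and a tie indicator; C − D, n₀, n₁ and n₂
for every feature pair are then four matrix products, accumulated over
sample-pair chunks to bound memory. This is algebraically identical to the
per-pair statistic (tests verify equality to 1e-12 against brute-force
pair enumeration) but runs in a handful of BLAS calls — about 13 s for
600 × 2000 features over 132 samples on one CPU.

**Degree filter.** A feature is retained iff ≥ `min_partners` (default 2)
features of the other ome exceed |τ| > `tau_min` (default 0.4, strict, on
the absolute value). Both omes are evaluated on the full matrix and the
filters applied simultaneously — one pass, no iterative re-filtering — so
the retained set is order-independent.

**Dual clustering.** Each retained protein is represented by its τ vector
over retained lipids (and vice versa), with missing τ set to 0 (absence of
association) for distance purposes only. Average-linkage hierarchical
clustering on Euclidean distances fixes the heatmap leaf order; k-means
(25 restarts, fixed seed) fixes the labels, which are renumbered by the
leaf position of each cluster's medoid so repeated runs are bit-identical.
Defaults are k = 18 protein and 13 lipid clusters (14 is available as a
flag; both conventions appear in practice and neither is claimed
canonical).

**Enrichment.** Cluster × term 2×2 tables over the universe of retained
features (configurable to all quantified features), two-sided Fisher exact
p by the probability-mass rule (tables whose probability is ≤ the observed
one within relative tolerance 1e-7, the R convention), Benjamini–Hochberg
q across all tested pairs, and a minimum overlap of a ≥ 2 before testing.
Lipid classes parsed from shorthand names act as terms for the lipid omes.
"Top partners" are the n largest-|τ| proteins per lipid (ties broken
lexicographically), aggregated into a frequency table.

**Signatures.** For cluster c and genotype g, each member feature's
replicate mean (in log₂) is de-logged — the geometric mean on the linear
scale — summed over the cluster, and the signature is
log₂(sum_g / sum_control). Summing is done on the linear scale because a
"summed cluster abundance" is a sum of intensities, not of logarithms.
Features unobserved in either genotype are dropped pairwise and
`n_features` records the count used. The control against itself is exactly
0, and adding a constant in log₂ space (a global intensity rescaling)
cancels.

**Outliers.** Per feature, genotype summaries (replicate means) are scored
with a robust z: (value − median)/(1.4826 · MAD), MAD floored at 1e-9 so a
constant vector yields z = 0 everywhere rather than an error; |z| ≥ 2.5
flags an outlier genotype. Median/MAD was chosen as the minimal defensible
robust statistic; both threshold and statistic are config-exposed. At
least 5 genotype summaries are required.

**Chain-length summaries.** Lipids are ranked ascending by log₂FC
(mid-ranks for ties; percentile = rank/n). Per class the table reports the
median fold change, the median percentile, and medians split at 20 total
carbons (short < 20 ≤ long, configurable); species with unknown carbon
counts are excluded from the split and counted.

## Synthetic generator: what it emulates and what it does not

The generator emulates a knockout-panel design: 33 genotypes (one control
plus 32 knockouts) × 4 replicate cultures, 2000 proteins and 600 lipids
with log₂ baselines ~N(20, 2²) and N(18, 2²). Each of 5 planted modules
has one latent activity per sample,
z[m, s] = effect · 1[genotype(s) affected] + N(0, latent_sd),
and module features read base + loading · z + N(0, noise_sd); background
features are independent noise. Module lipids are drawn with 80% purity
from a per-module lipid class, and protein annotation terms align with
modules (plus random decoys), so class and term enrichments are
recoverable against ground truth. Missingness is completely at random
(default 5%).

Parameter choices where no external value existed:

- `latent_sd = 0.5` log₂ — replicate-level pathway variation of ~1.4-fold,
  typical for quadruplicate cultured-cell designs. Larger values inflate
  within-module correlation but make genotype-mean signatures noisier;
  0.5 is a realistic middle.
- `loading = 1.0` for every module feature (a range is config-exposed).
  With unit loadings the planted genotype effect δ is exactly the
  per-feature log₂ shift, so "recovering δ" is well defined; heterogeneous
  loadings would scale the shift per feature.
- Module sizes 100 proteins / 40 lipids × 5 modules; 3 affected knockout
  genotypes per module, disjoint across modules, never the control.
- `noise_sd = 0.3` log₂ measurement noise and effect δ = 1.0 log₂ follow
  the stated design of the recovery experiments.

What a green recovery test establishes: under monotone latent coupling
with Gaussian noise and MCAR missingness, the pipeline retains ≥ 90% of
planted and ≤ 10% of background features and recovers planted modules with
ARI ≥ 0.8. What it does not establish: behaviour under intensity-dependent
missingness, batch effects, correlated background (co-regulated pathways
outside modules), non-monotone couplings, or sign-mixed modules — none of
which the generator produces. A scaled-down preset (8 genotypes × 3
replicates, 300 proteins, 120 lipids) ships for fast test runs; note its
24-sample null τ distribution is wide (sd ≈ 0.15), so background features
pass the 0.4 filter far more often than at the full 132-sample design —
degree-filter specificity claims hold only at full scale.

## Numerical choices

- Strict inequality |τ| > 0.4 in the filter; τ clipped to [−1, 1] after
  the vectorised computation to absorb float roundoff.
- Sample-pair sign/validity products are accumulated in float32 matmuls
  (counts < 2²⁴, hence exact) and divided in float64.
- `min_overlap = 8` complete samples: τ on fewer points is noise-dominated.
- k-means ties: 25 restarts, best inertia, fixed `random_state`; cluster
  ids renumbered by medoid leaf order; panel k-means labels renumbered by
  first occurrence.
- Fisher odds ratio is the sample odds ratio ad/bc (∞ when bc = 0 and
  ad > 0, undefined 0/0 → NaN).
- Degenerate inputs: empty retained sets are warnings with structured
  empty results, not errors; k = 1 clustering returns all-ones labels; a
  lipid with all-missing τ is excluded from top-partner tables with a
  warning.

## Signature-recovery variance

With 4 replicates, a genotype's module mean carries latent noise of
sd latent_sd/2 ≈ 0.25 log₂, and the KO − control difference ≈ 0.35 log₂
per planted (module, genotype) pair. The recovery check therefore
averages over all 15 planted pairs of the full design and 20 seeds
(SE ≈ 0.03), and its ±0.1 tolerance is a statement about the mean, not
about single-pair precision.

## Known limitations

- Kendall τ p-values are deliberately not computed (the degree filter is a
  magnitude threshold, not a significance test).
- GO term structure is flat: no ancestor propagation.
- The τ TSV reader used by the standalone `network` CLI subcommand does
  not restore per-pair sample counts (they are not persisted in the TSV).
- Replicate-level correlation is the default; genotype-mean profiles are a
  config switch, and the two can differ materially when replicate noise is
  large.
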