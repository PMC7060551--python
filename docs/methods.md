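# Methods

This note documents the statistical models behind each pipeline stage, the
parameters that matter, the design choices made where the design was open,
what the synthetic-data generator does and does not emulate, and the known
limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and peak geometry

All coordinates are BED-convention 0-based half-open `[start, end)`.
Adjacent intervals (`[0,10)`, `[10,20)`) do not overlap. narrowPeak summit
offsets (column 10) are relative to `start`; −1 means absent.

* **Tn5 cut sites.** A read is reduced to the transposase insertion point:
  forward-strand reads at `start + 5`, reverse-strand reads at `end − 4`
  (the conventional offsets for the 9-bp Tn5 duplication). Unstranded reads
  are an error — the cut site is undefined.
* **Summit splitting.** A peak with k summits becomes k sub-peaks with
  boundaries at `floor((s_i + s_{i+1})/2)`, assigned to the left sub-peak's
  exclusive end, so the sub-peaks exactly tile the parent. For base-adjacent
  summits the boundary is clamped to `s_i + 1` so no sub-peak is empty.
  Sub-peak names get deterministic `_s1.._sk` suffixes.
* **TSS distance.** Distance from a peak to a TSS marker at coordinate p is
  0 when the marker lies inside the peak, otherwise the distance to the
  nearer edge coordinate (`start − p` or `p − end`). This convention is
  fixed by the tie behaviour we want: markers one base outside either edge
  are equidistant. Ties go to the smaller TSS coordinate. The convention is
  symmetric under mirroring of marker coordinates (p → L − p), not under
  base-level mirroring, which is off by one on one side.
* **Peak classes.** Promoter: the peak overlaps an H3K4me3 peak that itself
  overlaps a TSS of an expressed gene. Enhancer: the peak overlaps an
  H3K27ac peak and its nearest TSS is more than the exclusion radius
  (default 2000 bp) away. Otherwise unknown. Promoter precedence when both
  rules hold. Classification is total and deterministic.

## Differential accessibility (negative-binomial Wald engine)

Counts `k_ij` (peak i, sample j) are modelled as negative binomial with mean
`s_j · q_ig` (size factor × group rate) and dispersion α, so
`Var = μ + α μ²`.

* **Size factors** are median-of-ratios: the reference is the geometric mean
  across samples over peaks with no zero count; each sample's factor is the
  median ratio to the reference. If no peak is all-nonzero the function
  errors and points to a pseudo-reference fallback rather than silently
  changing the estimator.
* **Group rates** are `q̂_g = Σ_j k_ij / Σ_j s_j` per group, with a 0.5-count
  continuity correction when a group is all zeros; `log2fc = log₂(q̂_A/q̂_B)`.
* **Dispersion.** Per-peak method-of-moments estimates (pooled within-group
  variance of normalized counts, floored at 1e-4) are noisy at 2–5
  replicates: using them directly makes a normal-reference Wald test badly
  anticonservative, while referring the statistic to a t distribution with
  the residual degrees of freedom is calibrated but bounds attainable
  p-values far above the 5×10⁻⁵ signature threshold at realistic replicate
  counts. The engine therefore shares information across peaks: the moment
  estimates are regressed on a parametric mean-dispersion trend
  `α(μ) = a₀ + a₁/μ` and the fitted trend value at each peak's mean is the
  working dispersion (floor kept). With fewer than 20 usable peaks the raw
  per-peak estimates are used. This is the same resolution dispersion-
  shrinkage engines adopt, in its simplest form.
* **Test.** Wald statistic `log(q̂_A/q̂_B) / SE` with
  `SE² = (1/q̂_A + α)/n_A + (1/q̂_B + α)/n_B`, two-sided normal reference;
  BH adjustment over all peaks. All-zero peaks are flagged degenerate with
  p = 1 and log2fc = 0. The engine is pluggable (`counts.ENGINES`); any
  callable with the same signature can replace it.

Calibration, measured by the test suite at the study design (2 parental vs
4 metastatic replicates, 1000 peaks, NB mean 50, dispersion 0.1): type-I
error at nominal 0.05 stays within [0.03, 0.07]; 8-fold planted peaks
(mean 100, dispersion 0.05) are recovered with ≥ 90% power at padj < 0.05.

## Normalization

* **log-CPM.** With library sizes `L_j` and prior count `prior` (default 5),
  the scaled prior is `π_j = prior · L_j / mean(L)` and the value is
  `log₂((count + π_j) / (L_j + 2π_j) · 10⁶)`.
* **Quantile normalization.** Each column's sorted values are replaced by
  the across-column mean of sorted values, preserving ranks; tied values
  receive the mean of their target values. The operation is idempotent.
* **BH adjustment** is the step-up procedure with the cumulative-minimum
  monotonicity enforcement, returned in input order.

## metATAC scoring

The signature is the peak set with padj < α (default 5×10⁻⁵; 0.05 for
within-cell-line analyses) in the metastatic-vs-parental contrast, computed
on the shared peak universe after log-CPM + quantile normalization. Parental
and metastatic signal sets are arithmetic means over the respective
replicate columns restricted to the signature; the organotropic variants are
the same code path with the metastatic replicate list restricted to one
sub-population. A patient's score is `S = r_met − r_par + 1 ∈ [−1, 3]`
(Pearson correlations over signature peaks). S is invariant to positive
affine transforms of the patient vector. Constant vectors are an error, not
silently dropped; patient alignment to the signature is strict, with no
imputation. Median stratification sends scores equal to the median to the
low stratum; an all-tied cohort is an error.

## Enhancer–promoter linkage

Anchors are assigned to the nearest consensus peak by interval gap
(0 when overlapping, edge-to-edge otherwise), within 2000 bp; ties go to the
smaller peak start. Pairs with an unassigned anchor, and pairs whose anchors
collapse onto one peak, are dropped. Reproducibility is the intersection of
unordered link sets across all provided replicates (generalizing "present in
both replicates"). Enhancer↔promoter links emit one (gene, enhancer) pair per
gene whose TSS is covered by the H3K4me3 overlap of the promoter peak.
The shuffle null permutes the gene side only, preserving the enhancer
multiset and per-enhancer degree, deterministically per seed. The
fold-change correlation is Pearson over one (enhancer log2FC, gene log2FC)
pair per link and requires ≥ 3 complete pairs.

## Motif-cluster enrichment

Occurrences with confidence ≤ 0 are discarded at load (strict inequality);
TFs missing from the cluster map abort the load with a report, keeping the
map total. The counting unit is the peak: a cluster is present if ≥ 1
occurrence of any member TF overlaps the peak. Foreground peaks are the
concordant regulatory regions: padj < 0.05 in the requested direction and
linked (as enhancer via loops, or as promoter directly) to ≥ 1 gene with
padj < 0.05 changing in the same direction. The test is the upper-tail
(over-representation) hypergeometric probability against the consensus-peak
background, with BH across the clusters tested in one (contrast, direction)
run; gained and lost directions are tested separately. Enrichment is
invariant to peak relabeling and input order. The packaged cluster map is a
small TSV (tf_name, cluster_id, cluster_label) the user can regenerate from
any motif-similarity clustering.

## Survival analysis

Expression is z-scored per gene within each dataset (sample sd, n−1) before
merging, which removes per-dataset location/scale batch effects; genes
constant within a dataset become missing with a warning. Median splits use
the same ties-low rule as score stratification. The two-group log-rank
statistic is referred to χ²₁. Cox proportional-hazards fits use the Efron
tie approximation and report `exp(coef)` with 95% Wald intervals (lifelines
backend). Site-specific endpoints treat relapse at other sites as censoring
at that time — an explicit assumption, not a claim about any source data.
The model errors rather than fitting when a covariate is constant or events
are fewer than coefficients. The per-TF screen median-splits each TF,
runs log-rank and the adjusted Cox fit, BH-adjusts across screened TFs,
records per-TF failures without aborting, and flags concordance when the
hazard direction matches the motif direction (gained & HR > 1, or
lost & HR < 1).

## Synthetic data: what it emulates, and what it does not

The generator is a pure function of (`FixtureSpec`, seed); identical bytes
on re-run. Defaults (the simulated study conditions):

| parameter | default | meaning |
|---|---|---|
| chrom_sizes | 2 × 8 Mb | toy genome; one peak per 8 kb slot |
| n_peaks / fractions | 1500; 0.4 promoter, 0.4 enhancer, 0.2 unknown | peak universe |
| n_replicates | 2 | per cell population; metastatic group = 2 sub-populations × 2 |
| nb_mean / nb_dispersion | 50 / 0.05 | NB count model (lognormal per-peak baselines, sdlog 0.5) |
| frac_differential / log2fc | 0.2 / ±2 | planted accessibility changes |
| library_sd | 0.15 | lognormal per-sample depth factors |
| n_links / β / σ / spurious | 500 / 1.0 / 0.5 / 0.3 | loops; gene log2FC = β·enhancer log2FC + N(0, σ) |
| fg_rate / bg_rate / zero-conf | 0.8 / 0.1 / 0.1 | planted motif cluster; 10 decoy clusters at 0.15 |
| n_patients / noise | 500 / 0.5 | patient signal = (1−w)·par + w·met + N(0, noise), w ~ U(0,1) |
| baseline hazard / logHR / censoring | 0.02 per month / 0.7 per unit w / U(0,120) months | exponential relapse times |

Slot placement guarantees the class rules exactly (promoter peaks carry a
TSS and an H3K4me3 peak; enhancers carry H3K27ac and are > 2 kb from every
TSS), so peak classification has a zero-ambiguity truth — recovery there
checks the rule implementation, not robustness to annotation noise. Each
linked gene has one dominant enhancer; spurious anchor pairs are
replicate-unique by construction, so perfect removal checks the filter, not
loop-calling accuracy. Dispersion is shared within a fixture (real data has
per-peak dispersion); covariates are independent of the latent weight, so
adjusted and unadjusted hazard estimates coincide in expectation. None of
the generators simulate read-level data, sequence content, fragment-length
structure, GC or mappability bias, or correlated peaks — passing tests
therefore demonstrate correctness of the algorithms under the stated
statistical model, not performance on real sequencing artifacts.

## Simulation sizes used by tests and the acceptance script

Chosen to make Monte-Carlo error small relative to the bands being checked:
null calibration and power on 1000-peak fixtures; Cox hazard-ratio recovery
as the geometric mean of 5 fits at n = 1000 with baseline hazard 0.05/month
(high event fraction keeps the sampling sd of the estimate well inside the
[1.7, 2.3] recovery band); CI coverage over 50 null cohorts of n = 500;
median-split log-rank power over 100 seeded cohorts (n = 500 each) — at
these conditions the true power is ≈ 0.88, so 20-seed estimates are too
noisy to compare against a 0.8 bound while 100-seed estimates are not.

## Known limitations

* The NB engine offers no fold-change shrinkage, independent filtering, or
  outlier handling; exact numerical parity with any external differential
  package is not claimed.
* The trend dispersion assumes a monotone mean-dispersion relation; fixtures
  with strongly bimodal dispersion would be better served by a per-peak
  engine plugged into `counts.ENGINES`.
* Quantile normalization assumes comparable distributions across samples;
  it will erase genuine global accessibility shifts.
* The linkage stage consumes called anchor pairs; it does not assess loop
  significance and inherits whatever anchor resolution the caller provides.
* Survival tooling assumes proportional hazards and independent censoring;
  site-specific censoring of other-site relapses ignores competing risks.
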