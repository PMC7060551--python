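# metachrom

Integrative chromatin-accessibility analysis of metastatic breast-cancer
models: a tested, reusable implementation of the analysis pipeline that links
ATAC-seq differential accessibility in parental vs. metastatic cell
populations to patient outcomes — via a chromatin-accessibility signature
score (metATAC), HiChIP-derived enhancer–promoter linkage, transcription-factor
motif-cluster enrichment, and metastasis-free-survival analysis.

It is written for computational biologists who have peak-level inputs (BED /
narrowPeak peaks with summits, per-sample cut-site count matrices, BEDPE
anchor pairs, motif-occurrence BED files, cohort expression/outcome tables)
and want the downstream integration without re-deriving each step.

## The analyses

**Differential accessibility.** Tn5 cut sites (+5 bp forward / −4 bp reverse
from read 5′ ends) are counted over a consensus peak set (multi-summit peaks
split at summits). A self-contained negative-binomial engine tests each peak:
median-of-ratios size factors, per-peak moment dispersion estimates shrunk to
a parametric mean-dispersion trend α(μ) = a₀ + a₁/μ, and a Wald test on the
group log₂ fold-change with Benjamini–Hochberg correction.

**metATAC score.** Signature peaks are those with adjusted p < 5×10⁻⁵ in the
metastatic-vs-parental contrast. With mean normalized profiles over the
signature, *par* and *met*, each patient's accessibility vector x gets

    S = r(x, met) − r(x, par) + 1

where r is the Pearson correlation; S ∈ [−1, 3], and S > 1 means the
patient's open chromatin resembles the metastatic populations more than the
parental line. Cohorts are stratified at the median of S (ties go low).

**Enhancer–promoter linkage.** HiChIP anchors are assigned to the nearest
consensus ATAC peak within 2 kb; only peak–peak links found in every
replicate are kept. Peaks are classed as promoters (overlap an H3K4me3 peak
that covers a TSS), enhancers (overlap H3K27ac and lie > 2 kb from every
expressed-gene TSS), or unknown. Enhancer↔promoter links yield
(gene, enhancer) pairs; a gene-side shuffle provides the null for the
enhancer-change vs expression-change correlation.

**Motif-cluster enrichment.** Motif occurrences (confidence > 0) are
collapsed into similarity clusters; a cluster is "present" in a peak if any
member TF occurrence overlaps it. Concordant regulatory regions (significant
peaks linked to significant genes changing in the same direction) are tested
against the consensus-peak background with upper-tail hypergeometric tests,
BH-corrected per direction; significant clusters are re-expanded to member
TFs.

**Survival.** Expression tables are z-scored per gene within each dataset
before merging; patients are median-split per gene; groups are compared with
the two-group log-rank test and a covariate-adjusted Cox proportional-hazards
model (Efron ties, 95% Wald CI). Site-specific analyses censor relapse at
other sites.

**Synthetic data.** Every input the pipeline consumes can be generated, with
truth tables, from a seeded `FixtureSpec`: a toy genome with known peak
classes, negative-binomial counts with planted fold-changes, anchor pairs
with replicate-unique spurious loops, expression coupled to linked-enhancer
changes, a motif cluster planted in foreground peaks, and patient cohorts
whose relapse hazard is log-linear in a latent metastatic-likeness weight.

## Worked example

```python
from metachrom.synthetic_data import FixtureSpec, gen_all
from metachrom import counts, metatac, survival

fix = gen_all(FixtureSpec(seed=0), "fixtures/")
cm = fix["counts"]
da = counts.nb_differential(cm, ("met", "par"))
norm = counts.quantile_normalize(counts.cpm_log(cm))
sig_peaks = metatac.select_signature_peaks(da, alpha=5e-5)
sig = metatac.build_signal_sets(
    norm, cm.group_samples("par"), cm.group_samples("met"), sig_peaks
)
scores, _ = metatac.score_cohort(fix["cohort_signal"], sig)
frame = metatac.scores_to_frame(scores)
strata = metatac.stratify_median(frame["s"].to_numpy())
chi2, p = survival.logrank(
    strata, fix["cohort_clinical"]["time"], fix["cohort_clinical"]["event"]
)
print(f"{len(sig_peaks)} signature peaks at padj < 5e-5")
print(frame.head(3).round(3))
print(f"log-rank chi2 = {chi2:.1f}, p = {p:.2e}")
```

prints

```
232 signature peaks at padj < 5e-5
            r_par  r_met      s
patient_id
pt_0000     0.322  0.913  1.591
pt_0001     0.773  0.487  0.715
pt_0002     0.779  0.459  0.681
log-rank chi2 = 20.8, p = 5.14e-06
```

Of the 1500 simulated peaks, 232 pass the signature threshold. Patient
`pt_0000` correlates much more strongly with the metastatic profile
(S = 1.59) than `pt_0001` (S = 0.72); splitting the 500-patient cohort at
the median score separates relapse-free survival decisively (log-rank
p ≈ 5×10⁻⁶), recovering the planted hazard structure.

The same stages are available from the shell:

```sh
metachrom synth all --seed 0 --out fixtures/
metachrom counts diff --counts fixtures/counts.tsv --meta fixtures/samples.tsv \
    --contrast met:par --out diff.tsv
metachrom metatac build --diff diff.tsv --norm norm.tsv \
    --par par_1,par_2 --met met_1,met_2,met_3,met_4 --alpha 5e-5 --out sig.tsv
metachrom metatac score --signature sig.tsv --cohort fixtures/cohort_signal.tsv \
    --out scores.tsv
metachrom linkage build --peaks fixtures/peaks.bed \
    --bedpe fixtures/rep1.bedpe --bedpe fixtures/rep2.bedpe --out links.tsv
metachrom motifs enrich --foreground fg.txt --background fixtures/peaks.bed \
    --motifs fixtures/motifs.bed --clusters fixtures/clusters.tsv --out enrich.tsv
```

All stages are deterministic: re-running with the same inputs and seed
produces byte-identical files.

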