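"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure of the real inputs on a toy
genome: non-overlapping peaks of known enhancer/promoter/unknown class
(promoters co-located with a TSS and an H3K4me3 peak, enhancers with H3K27ac
and > 2 kb from every TSS), negative-binomial peak counts with planted group
fold-changes, chromatin-loop anchor pairs with replicate-unique spurious
interactions, gene expression changes coupled to linked-enhancer
accessibility, motif occurrences of a cluster planted preferentially in
foreground peaks, and patient cohorts whose accessibility is a noisy mixture
``(1 - w) * parental + w * metastatic`` of the two signal profiles and whose
relapse hazard is log-linear in the latent metastatic-likeness weight ``w``.

Every generator is a pure function of the :class:`FixtureSpec` (including
its seed): re-running produces byte-identical outputs.  Truth tables are
returned alongside every fixture so each pipeline stage has a recovery test.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .counts import CountMatrix, cpm_log, quantile_normalize
from .intervals import GenomicInterval, PeakSet, write_bed
from .linkage import AnchorPairSet, write_bedpe
from .metatac import SignalSet
from .motifs import ClusterMap, MotifOccurrence

__all__ = [
    "FixtureSpec",
    "gen_genome",
    "gen_counts",
    "gen_links_and_expression",
    "gen_motif_bed",
    "gen_cohort",
    "gen_all",
]

SLOT_BP = 8000  # one peak per slot keeps inter-slot TSS distances > 2 kb


@dataclass
class FixtureSpec:
    """Parameters of one synthetic study; all generators read from here."""

    seed: int = 0
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 8_000_000, "chr2": 8_000_000}
    )
    n_peaks: int = 1500
    frac_promoter: float = 0.4
    frac_enhancer: float = 0.4
    # counts
    n_replicates: int = 2
    nb_mean: float = 50.0
    nb_dispersion: float = 0.05
    frac_differential: float = 0.2
    log2fc_magnitude: float = 2.0
    library_sd: float = 0.15
    # linkage
    n_links: int = 500
    linkage_coupling: float = 1.0  # beta
    linkage_noise: float = 0.5  # sigma of gene log2FC around beta * enhancer
    frac_spurious: float = 0.3
    max_anchor_jitter: int = 300
    # motifs
    fg_rate: float = 0.8
    bg_rate: float = 0.1
    decoy_rate: float = 0.15
    n_decoy_clusters: int = 10
    zero_conf_frac: float = 0.1
    # cohort
    n_patients: int = 500
    cohort_noise: float = 0.5
    baseline_hazard: float = 0.02  # events per month at w = 0
    log_hr_w: float = 0.7  # log hazard ratio per unit w
    censor_max: float = 120.0  # uniform censoring horizon, months

    def __post_init__(self) -> None:
        fracs = (
            self.frac_promoter, self.frac_enhancer, self.frac_differential,
            self.fg_rate, self.bg_rate, self.decoy_rate, self.zero_conf_frac,
            self.frac_spurious,
        )
        if any(not (0 <= f <= 1) for f in fracs):
            raise ValueError("all fractions must lie in [0, 1]")
        if self.frac_promoter + self.frac_enhancer > 1:
            raise ValueError("frac_promoter + frac_enhancer must be <= 1")
        if min(self.nb_mean, self.nb_dispersion, self.baseline_hazard) <= 0:
            raise ValueError("rates must be positive")

    @classmethod
    def from_yaml(cls, path) -> "FixtureSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _rng(spec: FixtureSpec, stage: str) -> np.random.Generator:
    """Independent deterministic stream per (seed, stage)."""
    return np.random.default_rng([spec.seed, zlib.crc32(stage.encode())])


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def gen_genome(spec: FixtureSpec) -> dict:
    """Toy genome: peaks, TSS, histone-mark peaks, and true classes.

    Peaks occupy one slot of ``SLOT_BP`` each, so peaks never overlap and
    every enhancer lies > 2 kb from every TSS by construction.  Promoter
    peaks carry a TSS at their center and an overlapping H3K4me3 peak;
    enhancer peaks carry an overlapping H3K27ac peak; unknown peaks carry
    neither mark.
    """
    rng = _rng(spec, "genome")
    slots = []
    for chrom, size in sorted(spec.chrom_sizes.items()):
        n_slots = size // SLOT_BP
        slots += [(chrom, i * SLOT_BP) for i in range(n_slots)]
    if spec.n_peaks > len(slots):
        raise ValueError(
            f"chromosomes fit {len(slots)} peaks; {spec.n_peaks} requested"
        )
    chosen = [slots[i] for i in sorted(rng.choice(len(slots), spec.n_peaks, replace=False))]

    n_prom = int(round(spec.frac_promoter * spec.n_peaks))
    n_enh = int(round(spec.frac_enhancer * spec.n_peaks))
    classes = np.array(
        ["promoter"] * n_prom
        + ["enhancer"] * n_enh
        + ["unknown"] * (spec.n_peaks - n_prom - n_enh)
    )
    rng.shuffle(classes)

    peaks, tss, k27, k4 = [], [], [], []
    truth_rows = []
    gene_n = 0
    for i, ((chrom, slot_start), cls) in enumerate(zip(chosen, classes)):
        width = int(rng.integers(300, 701))
        start = slot_start + 1000 + int(rng.integers(0, 501))
        end = start + width
        pid = f"peak_{i:05d}"
        peaks.append(GenomicInterval(chrom, start, end, ".", pid))
        gene = ""
        if cls == "promoter":
            gene_n += 1
            gene = f"gene_{gene_n:04d}"
            pos = (start + end) // 2
            tss.append(GenomicInterval(chrom, pos, pos + 1, "+", gene))
            k4.append(
                GenomicInterval(chrom, start - 200, end + 200, ".", f"k4_{i:05d}")
            )
        elif cls == "enhancer":
            k27.append(
                GenomicInterval(chrom, start - 200, end + 200, ".", f"k27_{i:05d}")
            )
        truth_rows.append({"peak_id": pid, "true_class": cls, "gene": gene})

    truth = pd.DataFrame(truth_rows).set_index("peak_id")
    return {
        "peaks": PeakSet(peaks),
        "tss": PeakSet(tss),
        "h3k27ac": PeakSet(k27),
        "h3k4me3": PeakSet(k4),
        "truth": truth,
    }


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def gen_counts(
    spec: FixtureSpec,
    peaks: PeakSet,
    groups: Mapping[str, Sequence[str]] | None = None,
    contrast_group: str = "met",
    stage: str = "counts",
) -> tuple[CountMatrix, pd.DataFrame]:
    """Negative-binomial peak counts with planted group fold-changes.

    Per-peak baseline means are log-normal around ``nb_mean``; a planted
    fraction of peaks has its mean multiplied by ``2**(+-log2fc_magnitude)``
    in the ``contrast_group`` samples.  Per-sample library factors are
    log-normal with sd ``library_sd``.  Returns the count matrix and a truth
    table (is_differential, direction, true_lfc).

    The default design mirrors the study layout: ``n_replicates`` parental
    samples against two metastatic sub-populations of ``n_replicates`` each,
    pooled into one contrast group.
    """
    rng = _rng(spec, stage)
    if groups is None:
        groups = {
            "par": [f"par_{r + 1}" for r in range(spec.n_replicates)],
            "met": [f"met_{r + 1}" for r in range(2 * spec.n_replicates)],
        }
    if contrast_group not in groups:
        raise KeyError(f"{contrast_group!r} not among groups {list(groups)}")
    peak_ids = [p.name for p in peaks]
    m = len(peak_ids)

    base_mean = np.exp(rng.normal(np.log(spec.nb_mean), 0.5, size=m))
    n_diff = int(round(spec.frac_differential * m))
    planted = np.zeros(m, dtype=bool)
    planted[rng.choice(m, n_diff, replace=False)] = True
    direction = np.where(planted, rng.choice([-1, 1], size=m), 0)
    true_lfc = direction * spec.log2fc_magnitude

    samples: list[str] = [s for cols in groups.values() for s in cols]
    lib = np.exp(rng.normal(0.0, spec.library_sd, size=len(samples)))
    data = {}
    r_nb = 1.0 / spec.nb_dispersion
    for j, sample in enumerate(samples):
        group = next(g for g, cols in groups.items() if sample in cols)
        mu = base_mean.copy()
        if group == contrast_group:
            mu = mu * np.power(2.0, true_lfc)
        mu = mu * lib[j]
        p_nb = r_nb / (r_nb + mu)
        data[sample] = rng.negative_binomial(r_nb, p_nb)
    counts = pd.DataFrame(data, index=peak_ids)
    meta = pd.DataFrame(
        {
            "group": [
                next(g for g, cols in groups.items() if s in cols)
                for s in samples
            ],
            "replicate": [
                list(groups[next(g for g, c in groups.items() if s in c)]).index(s) + 1
                for s in samples
            ],
        },
        index=samples,
    )
    truth = pd.DataFrame(
        {
            "is_differential": planted,
            "direction": direction,
            "true_lfc": true_lfc,
        },
        index=pd.Index(peak_ids, name="peak_id"),
    )
    return CountMatrix(counts, meta), truth


# ---------------------------------------------------------------------------
# loops and expression
# ---------------------------------------------------------------------------

def gen_links_and_expression(
    spec: FixtureSpec,
    genome: dict,
    counts_truth: pd.DataFrame,
    n_replicates: int = 2,
) -> dict:
    """True enhancer-promoter loops, spurious anchors, and coupled expression.

    ``n_links`` true links are drawn between enhancer peaks and promoter
    genes.  Each linked gene is regulated by one dominant enhancer (genes
    sampled without replacement; enhancers may serve several genes) and its
    expression log2FC is
    ``beta * (enhancer true log2FC) + Normal(0, sigma)``.  Each replicate's
    anchor pairs contain every true link (anchors jittered within
    ``max_anchor_jitter`` bp of their peaks) plus a replicate-unique set of
    spurious pairs that the reproducibility filter must remove entirely.
    """
    rng = _rng(spec, "links")
    truth = genome["truth"]
    peaks: PeakSet = genome["peaks"]
    enh_ids = list(truth.index[truth["true_class"] == "enhancer"])
    prom = truth[truth["true_class"] == "promoter"]
    if not enh_ids or prom.empty:
        raise ValueError("genome has no enhancers or no promoters")
    if spec.n_links > len(prom):
        raise ValueError(
            f"n_links={spec.n_links} exceeds the {len(prom)} promoter genes"
        )

    enh_pick = rng.choice(len(enh_ids), size=spec.n_links, replace=True)
    prom_pick = rng.choice(len(prom), size=spec.n_links, replace=False)
    link_list = sorted(
        (prom["gene"].iloc[p_i], enh_ids[e_i], prom.index[p_i])
        for e_i, p_i in zip(enh_pick, prom_pick)
    )

    enhancer_fc = counts_truth["true_lfc"].to_dict()
    gene_enh: dict[str, list[str]] = {}
    for gene, enh, _ in link_list:
        gene_enh.setdefault(gene, []).append(enh)
    all_genes = [g for g in prom["gene"]]
    gene_fc = {}
    for gene in sorted(all_genes):
        coupled = (
            spec.linkage_coupling
            * float(np.mean([enhancer_fc[e] for e in gene_enh[gene]]))
            if gene in gene_enh
            else 0.0
        )
        gene_fc[gene] = coupled + rng.normal(0.0, spec.linkage_noise)

    # synthetic differential-expression table: the test SE is a fraction of
    # the biological noise, so strongly coupled genes come out significant
    se = max(spec.linkage_noise / 2.0, 1e-6)
    genes_sorted = sorted(gene_fc)
    lfc = np.array([gene_fc[g] for g in genes_sorted])
    from scipy import stats as _st
    from .counts import bh_adjust as _bh
    p = 2 * _st.norm.sf(np.abs(lfc) / se)
    de = pd.DataFrame(
        {"log2fc": lfc, "p": p, "padj": _bh(p)},
        index=pd.Index(genes_sorted, name="gene_id"),
    )

    # anchors
    def _jitter(iv: GenomicInterval) -> GenomicInterval:
        d = int(rng.integers(-spec.max_anchor_jitter, spec.max_anchor_jitter + 1))
        return GenomicInterval(iv.chrom, max(0, iv.start + d), iv.end + d)

    true_pairs = sorted({tuple(sorted((e, pp))) for _, e, pp in link_list})
    all_ids = [pk.name for pk in peaks]
    n_spur = int(round(spec.frac_spurious * spec.n_links))
    spur_pool: list[tuple[str, str]] = []
    taken = set(true_pairs)
    while len(spur_pool) < n_spur * n_replicates:
        i, j = rng.choice(len(all_ids), size=2, replace=False)
        pair = tuple(sorted((all_ids[i], all_ids[j])))
        if pair not in taken:
            taken.add(pair)
            spur_pool.append(pair)

    reps = []
    for r in range(n_replicates):
        pairs = []
        for a, b in true_pairs:
            pairs.append((_jitter(peaks[a]), _jitter(peaks[b])))
        for a, b in spur_pool[r * n_spur:(r + 1) * n_spur]:
            pairs.append((_jitter(peaks[a]), _jitter(peaks[b])))
        reps.append(AnchorPairSet(f"rep{r + 1}", pairs))

    return {
        "replicates": reps,
        "gene_links": sorted({(g, e) for g, e, _ in link_list}),
        "gene_fc": gene_fc,
        "enhancer_fc": enhancer_fc,
        "de": de,
        "spurious_pairs": spur_pool,
        "true_pairs": true_pairs,
    }


# ---------------------------------------------------------------------------
# motifs
# ---------------------------------------------------------------------------

def gen_motif_bed(
    spec: FixtureSpec,
    peaks: PeakSet,
    foreground_ids: Sequence[str],
) -> tuple[list[MotifOccurrence], ClusterMap]:
    """Motif occurrences with one cluster planted in the foreground.

    The planted cluster occurs in ``fg_rate`` of foreground peaks and
    ``bg_rate`` of the rest; decoy clusters occur uniformly at
    ``decoy_rate``.  A ``zero_conf_frac`` fraction of records gets
    confidence 0 and must be removed by the loader's strict filter.
    """
    rng = _rng(spec, "motifs")
    fg = set(foreground_ids)
    planted_id = "C00"
    tf_to_cluster = {"TFPL1": planted_id, "TFPL2": planted_id}
    labels = {planted_id: "PLANTED-family"}
    for d in range(1, spec.n_decoy_clusters + 1):
        cid = f"C{d:02d}"
        labels[cid] = f"DECOY-family-{d}"
        tf_to_cluster[f"TFD{d:02d}A"] = cid
        tf_to_cluster[f"TFD{d:02d}B"] = cid
    cmap = ClusterMap(tf_to_cluster, labels)

    occs: list[MotifOccurrence] = []
    for peak in peaks:
        present = []
        rate = spec.fg_rate if peak.name in fg else spec.bg_rate
        if rng.random() < rate:
            present.append(planted_id)
        for d in range(1, spec.n_decoy_clusters + 1):
            if rng.random() < spec.decoy_rate:
                present.append(f"C{d:02d}")
        for cid in present:
            members = cmap.members(cid)
            tf = members[int(rng.integers(len(members)))]
            lo = peak.start + int(rng.integers(0, max(1, peak.width - 10)))
            conf = float(rng.uniform(0.2, 1.0))
            if rng.random() < spec.zero_conf_frac:
                conf = 0.0
            occs.append(
                MotifOccurrence(
                    GenomicInterval(peak.chrom, lo, lo + 10, "."), tf, conf
                )
            )
    return occs, cmap


def write_motif_bed(occs: Sequence[MotifOccurrence], path) -> None:
    with open(path, "w") as fh:
        for o in occs:
            fh.write(
                f"{o.interval.chrom}\t{o.interval.start}\t{o.interval.end}"
                f"\t{o.tf_name}\t{o.confidence:.4f}\t{o.interval.strand}\n"
            )


def write_cluster_map(cmap: ClusterMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("tf_name\tcluster_id\tcluster_label\n")
        for tf in sorted(cmap.tf_to_cluster):
            cid = cmap.tf_to_cluster[tf]
            fh.write(f"{tf}\t{cid}\t{cmap.cluster_label[cid]}\n")


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def gen_cohort(
    spec: FixtureSpec, sig: SignalSet, stage: str = "cohort"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Patient accessibility + survival cohort driven by a latent weight w.

    Each patient draws ``w ~ Uniform(0, 1)``; their signature-peak signal is
    ``(1 - w) * par + w * met + Normal(0, cohort_noise)``.  Event times are
    exponential with hazard ``baseline_hazard * exp(log_hr_w * w)`` and
    censoring is uniform on ``(0, censor_max)``.  Clinical covariates are
    drawn independently of w; two expression columns are included for screen
    tests: ``TF_RISK`` tracks w (so its high stratum relapses earlier) and
    ``TF_NULL`` is pure noise.
    """
    rng = _rng(spec, stage)
    n = spec.n_patients
    w = rng.uniform(0.0, 1.0, size=n)
    base = np.outer(1.0 - w, sig.par_signal) + np.outer(w, sig.met_signal)
    signal = base + rng.normal(0.0, spec.cohort_noise, size=base.shape)
    patients = [f"pt_{i:04d}" for i in range(n)]
    signal_df = pd.DataFrame(signal, index=patients, columns=sig.peak_ids)

    hazard = spec.baseline_hazard * np.exp(spec.log_hr_w * w)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.uniform(0.0, spec.censor_max, size=n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    site = rng.choice(["lung", "brain", "other"], size=n, p=[0.3, 0.3, 0.4])
    clin = pd.DataFrame(
        {
            "time": time,
            "event": event,
            "w": w,
            "age": rng.normal(58.0, 10.0, size=n),
            "er": rng.integers(0, 2, size=n),
            "pr": rng.integers(0, 2, size=n),
            "her2": rng.integers(0, 2, size=n),
            "subtype": rng.choice(
                ["LumA", "LumB", "Her2", "Basal"], size=n,
                p=[0.4, 0.25, 0.15, 0.2],
            ),
            "stage": rng.choice(["I", "II", "III"], size=n, p=[0.3, 0.5, 0.2]),
            "differentiation": rng.normal(0.0, 1.0, size=n),
            "chemo": rng.integers(0, 2, size=n),
            "TF_RISK": w + rng.normal(0.0, 0.3, size=n),
            "TF_NULL": rng.normal(0.0, 1.0, size=n),
        },
        index=patients,
    )
    for s in ("lung", "brain"):
        clin[f"time_{s}"] = time
        clin[f"event_{s}"] = ((event == 1) & (site == s)).astype(int)
    return signal_df, clin


# ---------------------------------------------------------------------------
# full fixture
# ---------------------------------------------------------------------------

def gen_all(spec: FixtureSpec, outdir: str | Path) -> dict:
    """Generate and write every fixture the pipeline consumes.

    The cohort's parental/metastatic signal profiles are built from the
    generated counts by the standard normalization (log-CPM then quantile
    normalization) restricted to the planted (truth) signature peaks, so the
    fixture is self-contained.  Returns the in-memory objects as a dict.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    genome = gen_genome(spec)
    counts, counts_truth = gen_counts(spec, genome["peaks"])
    loops = gen_links_and_expression(spec, genome, counts_truth)
    fg_truth = _true_foreground(counts_truth, loops, direction="up")
    occs, cmap = gen_motif_bed(spec, genome["peaks"], fg_truth)

    norm = quantile_normalize(cpm_log(counts))
    sig_peaks = list(counts_truth.index[counts_truth["is_differential"]])
    par_cols = counts.group_samples("par")
    met_cols = counts.group_samples("met")
    sig = SignalSet(
        sig_peaks,
        norm.loc[sig_peaks, par_cols].mean(axis=1).to_numpy(),
        norm.loc[sig_peaks, met_cols].mean(axis=1).to_numpy(),
    )
    cohort_signal, cohort_clin = gen_cohort(spec, sig)

    # write text fixtures
    write_bed(genome["peaks"], out / "peaks.bed")
    write_bed(genome["tss"], out / "tss.bed")
    write_bed(genome["h3k27ac"], out / "h3k27ac.bed")
    write_bed(genome["h3k4me3"], out / "h3k4me3.bed")
    genome["truth"].to_csv(out / "truth_peaks.tsv", sep="\t")
    counts.to_tsv(out / "counts.tsv", out / "samples.tsv")
    counts_truth.to_csv(out / "truth_counts.tsv", sep="\t", float_format="%.6g")
    for rep in loops["replicates"]:
        write_bedpe(rep, out / f"{rep.replicate_id}.bedpe")
    pd.DataFrame(loops["gene_links"], columns=["gene_id", "enhancer_peak_id"]).to_csv(
        out / "truth_gene_links.tsv", sep="\t", index=False
    )
    loops["de"].to_csv(out / "gene_de.tsv", sep="\t", float_format="%.6g")
    write_motif_bed(occs, out / "motifs.bed")
    write_cluster_map(cmap, out / "clusters.tsv")
    sig.to_tsv(out / "signature_truth.tsv")
    cohort_signal.to_csv(out / "cohort_signal.tsv", sep="\t", float_format="%.6g")
    cohort_clin.to_csv(out / "cohort_clinical.tsv", sep="\t", float_format="%.6g")
    spec.to_yaml(out / "fixture_spec.yaml")

    return {
        "genome": genome,
        "counts": counts,
        "counts_truth": counts_truth,
        "loops": loops,
        "motifs": (occs, cmap),
        "signal_set": sig,
        "cohort_signal": cohort_signal,
        "cohort_clinical": cohort_clin,
        "foreground_truth": fg_truth,
    }


def _true_foreground(
    counts_truth: pd.DataFrame, loops: dict, direction: str = "up"
) -> list[str]:
    """Truth-level concordant regulatory regions (generator's own bookkeeping).

    A planted peak in the requested direction that is linked (as enhancer)
    to a gene whose coupled expression change has the same sign.
    """
    sign = 1 if direction == "up" else -1
    gene_fc = loops["gene_fc"]
    fg = []
    enh_genes: dict[str, set[str]] = {}
    for g, e in loops["gene_links"]:
        enh_genes.setdefault(e, set()).add(g)
    for pid, row in counts_truth.iterrows():
        if not row["is_differential"] or row["direction"] != sign:
            continue
        genes = enh_genes.get(pid, set())
        if any(sign * gene_fc[g] > 0 for g in genes):
            fg.append(pid)
    return fg
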