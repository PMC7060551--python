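"""Motif-occurrence handling and cluster-level hypergeometric enrichment.

Transcription-factor motif occurrences (genome-wide intervals with a
conservation-based confidence score) are filtered to confidence > 0 and
collapsed into motif clusters via a TF -> cluster map (motif-similarity
clustering; each cluster is displayed by its most common TF family).  The
unit of counting is the peak: a cluster is "present" in a peak when at least
one occurrence of any member TF overlaps it.  Enrichment of each cluster in
a foreground peak set against a background universe uses the upper-tail
hypergeometric test, BH-corrected across the clusters tested in one
(contrast, direction) run.  The foreground is the set of concordant
regulatory regions: significantly differential peaks linked (as enhancer via
chromatin loops, or as promoter directly) to a significantly differential
gene changing in the same direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .counts import bh_adjust
from .intervals import GenomicInterval, PeakSet, overlap_pairs

__all__ = [
    "MotifOccurrence",
    "ClusterMap",
    "EnrichmentResult",
    "load_cluster_map",
    "load_motif_bed",
    "clusters_per_peak",
    "select_regulatory_regions",
    "hypergeom_enrichment",
    "clusters_to_tfs",
    "compare_tf_sets",
]


@dataclass(frozen=True)
class MotifOccurrence:
    interval: GenomicInterval
    tf_name: str
    confidence: float


@dataclass
class ClusterMap:
    """Total mapping TF name -> cluster id, with display labels per cluster."""

    tf_to_cluster: dict[str, str]
    cluster_label: dict[str, str]

    def members(self, cluster_id: str) -> list[str]:
        return sorted(
            tf for tf, c in self.tf_to_cluster.items() if c == cluster_id
        )


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric outcome for one motif cluster.

    k of n foreground peaks contain the cluster, K of N background peaks do;
    ``p`` is the upper-tail (over-representation) probability.
    """

    cluster_id: str
    k: int
    n: int
    K: int
    N: int
    p: float
    padj: float
    direction: str


def load_cluster_map(path) -> ClusterMap:
    """Read a TSV (tf_name, cluster_id, cluster_label) into a ClusterMap."""
    df = pd.read_csv(path, sep="\t")
    t2c = dict(zip(df["tf_name"].astype(str), df["cluster_id"].astype(str)))
    labels = (
        df.drop_duplicates("cluster_id")
        .set_index("cluster_id")["cluster_label"]
        .astype(str)
        .to_dict()
    )
    return ClusterMap(t2c, labels)


def load_motif_bed(path, cluster_map: ClusterMap) -> list[MotifOccurrence]:
    """Load motif occurrences, keeping confidence > 0 and mapped TFs only.

    Records at confidence 0 are silently dropped (strict inequality); a TF
    absent from the cluster map aborts the load with a report of the unmapped
    names; malformed lines raise with their line number.
    """
    occs: list[MotifOccurrence] = []
    unmapped: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"line {lineno}: expected >= 5 columns")
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                tf = fields[3]
                conf = float(fields[4])
                strand = fields[5] if len(fields) > 5 else "."
            except (ValueError, IndexError) as exc:
                raise ValueError(f"line {lineno}: {exc}") from None
            if conf <= 0:
                continue
            if tf not in cluster_map.tf_to_cluster:
                unmapped.add(tf)
                continue
            occs.append(
                MotifOccurrence(
                    GenomicInterval(chrom, start, end, strand), tf, conf
                )
            )
    if unmapped:
        raise ValueError(
            f"{len(unmapped)} TFs absent from cluster map: "
            f"{sorted(unmapped)[:10]}"
        )
    return occs


def clusters_per_peak(
    peaks: PeakSet, occurrences: Sequence[MotifOccurrence],
    cluster_map: ClusterMap,
) -> dict[str, set[str]]:
    """Unique motif clusters occurring under each peak.

    A cluster is counted once per peak however many member-TF occurrences
    overlap it (>= 1 bp).  Every peak of the set appears in the result,
    possibly with an empty set.
    """
    occ_ivs = [
        GenomicInterval(
            o.interval.chrom, o.interval.start, o.interval.end,
            o.interval.strand, f"occ_{i:07d}",
        )
        for i, o in enumerate(occurrences)
    ]
    out: dict[str, set[str]] = {p.name: set() for p in peaks}
    if occ_ivs:
        occ_set = PeakSet(occ_ivs)
        for peak_id, occ_id in overlap_pairs(peaks, occ_set):
            o = occurrences[int(occ_id.split("_")[1])]
            out[peak_id].add(cluster_map.tf_to_cluster[o.tf_name])
    return out


def select_regulatory_regions(
    da: pd.DataFrame,
    de: pd.DataFrame,
    gene_links: Sequence[tuple[str, str]],
    promoter_peak_gene_map: Mapping[str, Sequence[str]],
    alpha: float = 0.05,
    direction: str = "up",
) -> list[str]:
    """Concordant regulatory regions for one direction of change.

    A peak is selected when it is significantly differential (padj < alpha)
    in the requested direction AND is linked -- as an enhancer through the
    chromatin-loop gene links, or as a promoter through the promoter-gene
    map -- to at least one gene that is significantly differential in the
    same direction.  ``da`` / ``de`` index peaks / genes and carry
    ``log2fc`` and ``padj`` columns.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    sign = 1.0 if direction == "up" else -1.0
    sig_genes = set(
        de.index[(de["padj"] < alpha) & (sign * de["log2fc"] > 0)]
    )
    peak_genes: dict[str, set[str]] = {}
    for gene, enh in gene_links:
        peak_genes.setdefault(enh, set()).add(gene)
    for peak, genes in promoter_peak_gene_map.items():
        peak_genes.setdefault(peak, set()).update(genes)
    selected = []
    sig_peaks = da.index[(da["padj"] < alpha) & (sign * da["log2fc"] > 0)]
    for peak in sig_peaks:
        if peak_genes.get(peak, set()) & sig_genes:
            selected.append(peak)
    return selected


def hypergeom_enrichment(
    foreground: Sequence[str],
    background: Sequence[str],
    cluster_sets: Mapping[str, set[str]],
    direction: str = "up",
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of each cluster in the foreground.

    With N background peaks of which K contain the cluster, and n foreground
    peaks of which k do, ``p = P(X >= k)`` for X hypergeometric(N, K, n).
    BH adjustment spans all clusters tested in the run.  Results are sorted
    by (p, cluster_id).
    """
    fg = set(foreground)
    bg = set(background)
    if not fg <= bg:
        raise ValueError("foreground must be a subset of the background")
    if len(bg) < 2:
        raise ValueError("background must contain >= 2 peaks")
    N, n = len(bg), len(fg)
    clusters = sorted({c for pid in bg for c in cluster_sets.get(pid, ())})
    rows = []
    for c in clusters:
        K = sum(1 for pid in bg if c in cluster_sets.get(pid, ()))
        k = sum(1 for pid in fg if c in cluster_sets.get(pid, ()))
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((c, k, K, min(p, 1.0)))
    padj = bh_adjust([r[3] for r in rows]) if rows else []
    results = [
        EnrichmentResult(c, k, n, K, N, p, float(q), direction)
        for (c, k, K, p), q in zip(rows, padj)
    ]
    return sorted(results, key=lambda r: (r.p, r.cluster_id))


def enrichment_to_frame(
    results: Sequence[EnrichmentResult], cluster_map: ClusterMap | None = None
) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "cluster": [r.cluster_id for r in results],
            "direction": [r.direction for r in results],
            "k": [r.k for r in results],
            "n": [r.n for r in results],
            "K": [r.K for r in results],
            "N": [r.N for r in results],
            "p": [r.p for r in results],
            "padj": [r.padj for r in results],
        }
    )
    if cluster_map is not None:
        df["member_tfs"] = [
            ",".join(cluster_map.members(r.cluster_id)) for r in results
        ]
    return df


def clusters_to_tfs(
    significant: Sequence[EnrichmentResult], cluster_map: ClusterMap
) -> dict[str, list[str]]:
    """Re-assign significant clusters to their member TFs, per direction."""
    out: dict[str, set[str]] = {}
    for r in significant:
        out.setdefault(r.direction, set()).update(
            cluster_map.members(r.cluster_id)
        )
    return {d: sorted(tfs) for d, tfs in out.items()}


def compare_tf_sets(
    tfs_a: Iterable[str], tfs_b: Iterable[str]
) -> dict[str, list[str]]:
    """Venn-style comparison of TF lists across two contrasts."""
    a, b = set(tfs_a), set(tfs_b)
    return {
        "shared": sorted(a & b),
        "a_only": sorted(a - b),
        "b_only": sorted(b - a),
    }
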