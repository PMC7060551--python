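"""HiChIP anchor-pair processing and enhancer-gene linkage.

Interaction anchors from each HiChIP replicate are assigned to the nearest
consensus ATAC peak within a maximum gap (default 2000 bp); pairs with an
unassignable anchor and pairs collapsing to a single peak are dropped; only
peak-peak links present in every replicate survive the reproducibility
filter.  Links joining an enhancer-class peak to a promoter-class peak yield
(gene, enhancer) associations for every gene whose TSS the promoter's
H3K4me3 overlap covers.  A shuffle null (permuting the gene side of the
links) provides the negative control for the enhancer-change /
expression-change correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, PeakClass, PeakSet

__all__ = [
    "AnchorPairSet",
    "LinkageSet",
    "read_bedpe",
    "assign_anchor",
    "pairs_to_peak_links",
    "enhancer_gene_links",
    "shuffle_links",
    "link_fc_correlation",
]


def _canonical(a: GenomicInterval, b: GenomicInterval):
    ka = (a.chrom, a.start, a.end)
    kb = (b.chrom, b.start, b.end)
    return (a, b) if ka <= kb else (b, a)


@dataclass
class AnchorPairSet:
    """Interaction anchor pairs from one HiChIP replicate.

    Pairs are canonicalized so the lexicographically smaller anchor comes
    first.
    """

    replicate_id: str
    pairs: list[tuple[GenomicInterval, GenomicInterval]]

    def __post_init__(self) -> None:
        self.pairs = [_canonical(a, b) for a, b in self.pairs]


@dataclass
class LinkageSet:
    """Replicate-reproducible peak-peak links (unordered, deduplicated)."""

    links: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.links = sorted({tuple(sorted(l)) for l in self.links})

    def to_frame(self, classes: Mapping[str, str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame(self.links, columns=["peakA", "peakB"])
        if classes is not None:
            df["classA"] = [classes.get(a, "unknown") for a in df["peakA"]]
            df["classB"] = [classes.get(b, "unknown") for b in df["peakB"]]
        return df


def read_bedpe(path, replicate_id: str) -> AnchorPairSet:
    """Read a >= 6 column BEDPE file of anchor pairs."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 6:
        raise ValueError("BEDPE requires >= 6 columns")
    pairs = []
    for row in df.itertuples(index=False):
        a = GenomicInterval(str(row[0]), int(row[1]), int(row[2]))
        b = GenomicInterval(str(row[3]), int(row[4]), int(row[5]))
        pairs.append((a, b))
    return AnchorPairSet(replicate_id, pairs)


def write_bedpe(pairs: AnchorPairSet, path) -> None:
    with open(path, "w") as fh:
        for a, b in pairs.pairs:
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\n"
            )


def _gap(a_start: int, a_end: int, b_start: np.ndarray, b_end: np.ndarray) -> np.ndarray:
    """Interval gap: 0 on overlap/adjacency boundary, else bp between edges."""
    left = b_start - a_end  # >= 0 when b entirely right of a
    right = a_start - b_end
    return np.maximum(0, np.maximum(left, right))


def assign_anchor(
    anchor: GenomicInterval, peaks: PeakSet, max_dist: int = 2000
) -> str | None:
    """Nearest consensus peak within ``max_dist`` bp of the anchor, or None.

    Distance is the interval gap (0 when overlapping); ties are broken by the
    smaller peak start coordinate.
    """
    arr = peaks.chrom_arrays(anchor.chrom)
    if arr is None:
        return None
    gaps = _gap(anchor.start, anchor.end, arr["start"], arr["end"])
    i = int(np.argmin(gaps))  # starts sorted ascending => smallest start wins ties
    if gaps[i] > max_dist:
        return None
    return str(arr["name"][i])


def pairs_to_peak_links(
    reps: Sequence[AnchorPairSet], peaks: PeakSet, max_dist: int = 2000
) -> LinkageSet:
    """Map anchor pairs to peak-peak links and keep reproducible ones.

    Each anchor maps to its nearest peak within ``max_dist``; pairs with an
    unassigned anchor or with both anchors on the same peak are dropped; the
    result is the intersection of the per-replicate unordered link sets.
    """
    if len(reps) < 2:
        raise ValueError("need >= 2 replicates for the reproducibility filter")
    rep_sets: list[set[tuple[str, str]]] = []
    for rep in reps:
        links: set[tuple[str, str]] = set()
        for a, b in rep.pairs:
            pa = assign_anchor(a, peaks, max_dist)
            pb = assign_anchor(b, peaks, max_dist)
            if pa is None or pb is None or pa == pb:
                continue
            links.add(tuple(sorted((pa, pb))))
        rep_sets.append(links)
    kept = set.intersection(*rep_sets)
    return LinkageSet(sorted(kept))


def enhancer_gene_links(
    links: LinkageSet,
    classes: Iterable[PeakClass],
    promoter_gene_map: Mapping[str, Sequence[str]],
) -> list[tuple[str, str]]:
    """(gene, enhancer) pairs from enhancer <-> promoter links.

    For each link joining an enhancer-class peak to a promoter-class peak,
    one pair is emitted per gene whose TSS the promoter peak's H3K4me3
    overlap covers.  Promoter-promoter and unknown-containing links stay in
    the LinkageSet but contribute nothing here.
    """
    cls = {c.peak_id: c.cls for c in classes}
    out: set[tuple[str, str]] = set()
    for a, b in links.links:
        ca, cb = cls.get(a, "unknown"), cls.get(b, "unknown")
        if {ca, cb} != {"enhancer", "promoter"}:
            continue
        enh, prom = (a, b) if ca == "enhancer" else (b, a)
        for gene in promoter_gene_map.get(prom, []):
            out.add((gene, enh))
    return sorted(out)


def shuffle_links(
    gene_links: Sequence[tuple[str, str]], seed: int
) -> list[tuple[str, str]]:
    """Permute the gene side of the links uniformly at random.

    The enhancer multiset and per-enhancer link counts are preserved;
    deterministic for a given seed.
    """
    if len(gene_links) < 2:
        raise ValueError("need >= 2 links to shuffle")
    rng = np.random.default_rng(seed)
    genes = [g for g, _ in gene_links]
    perm = rng.permutation(len(genes))
    return [(genes[perm[i]], e) for i, (_, e) in enumerate(gene_links)]


def link_fc_correlation(
    enhancer_fc: Mapping[str, float],
    gene_fc: Mapping[str, float],
    gene_links: Sequence[tuple[str, str]],
) -> tuple[float, float]:
    """Pearson correlation of enhancer vs gene fold-change across links.

    One (enhancer log2FC, gene expression log2FC) pair per link; links with
    either value missing are skipped.  Returns ``(r, two-sided p)``.
    """
    xs, ys = [], []
    for gene, enh in gene_links:
        if enh in enhancer_fc and gene in gene_fc:
            xs.append(enhancer_fc[enh])
            ys.append(gene_fc[gene])
    if len(xs) < 3:
        raise ValueError(f"only {len(xs)} complete pairs; need >= 3")
    x = np.asarray(xs)
    y = np.asarray(ys)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: constant fold-changes")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
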