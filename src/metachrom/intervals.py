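"""Genomic intervals, BED-family I/O, and peak-geometry operations.

All coordinates follow the BED convention: 0-based, half-open ``[start, end)``.
The operations here implement the geometry used by ATAC-seq / ChIP-seq
integration: Tn5 cut-site shifting (+5 bp on the forward strand, -4 bp on the
reverse strand), splitting multi-summit peaks into one sub-peak per summit,
interval overlap, distance to the nearest transcription start site (TSS), and
the operational enhancer/promoter classification of accessible regions
(promoter = overlaps an H3K4me3 peak that itself covers a TSS; enhancer =
overlaps H3K27ac and lies more than a promoter-exclusion radius from every
TSS of an expressed gene).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "PeakClass",
    "shift_tn5",
    "split_at_summits",
    "overlap_pairs",
    "nearest_tss",
    "classify_peak",
    "classify_peaks",
    "promoter_gene_map",
    "read_bed",
    "read_narrowpeak",
    "read_tss_bed",
    "write_bed",
]

_VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` with optional summits.

    ``summits`` are absolute 0-based positions of local signal maxima and must
    be strictly increasing and contained in the interval.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None
    summits: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.summits is not None:
            s = tuple(int(x) for x in self.summits)
            object.__setattr__(self, "summits", s)
            if any(not (self.start <= x < self.end) for x in s):
                raise ValueError(f"summit outside interval {self}")
            if any(b <= a for a, b in zip(s, s[1:])):
                raise ValueError("summits must be strictly increasing")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class PeakSet:
    """An ordered, name-indexed collection of :class:`GenomicInterval`.

    On construction intervals are normalized: sorted by (chrom, start, end)
    and indexed by unique name.  Unnamed intervals receive deterministic
    ``peak_<i>`` names in sorted order.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]):
        ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        named: list[GenomicInterval] = []
        for i, iv in enumerate(ivs):
            if iv.name is None:
                iv = GenomicInterval(
                    iv.chrom, iv.start, iv.end, iv.strand,
                    f"peak_{i:06d}", iv.score, iv.summits,
                )
            named.append(iv)
        names = [iv.name for iv in named]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate interval names: {dup[:5]}")
        self.intervals: list[GenomicInterval] = named
        self.id_index: dict[str, GenomicInterval] = {iv.name: iv for iv in named}
        # per-chromosome coordinate arrays for fast queries
        self._by_chrom: dict[str, dict[str, np.ndarray]] = {}
        for chrom in sorted({iv.chrom for iv in named}):
            sub = [iv for iv in named if iv.chrom == chrom]
            self._by_chrom[chrom] = {
                "start": np.array([iv.start for iv in sub], dtype=np.int64),
                "end": np.array([iv.end for iv in sub], dtype=np.int64),
                "name": np.array([iv.name for iv in sub], dtype=object),
            }

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, name: str) -> GenomicInterval:
        return self.id_index[name]

    def chroms(self) -> list[str]:
        return list(self._by_chrom)

    def chrom_arrays(self, chrom: str) -> dict[str, np.ndarray] | None:
        return self._by_chrom.get(chrom)

    def overlapping(self, query: GenomicInterval) -> list[GenomicInterval]:
        """All intervals sharing >= 1 bp with ``query`` (half-open)."""
        arr = self._by_chrom.get(query.chrom)
        if arr is None:
            return []
        hit = (arr["start"] < query.end) & (arr["end"] > query.start)
        return [self.id_index[n] for n in arr["name"][hit]]


@dataclass(frozen=True)
class PeakClass:
    """Operational regulatory class of one peak."""

    peak_id: str
    cls: str  # {"enhancer", "promoter", "unknown"}
    nearest_tss_gene: str | None
    tss_distance: float  # bp >= 0; +inf when no TSS shares the chromosome


def shift_tn5(read: GenomicInterval) -> GenomicInterval:
    """Reduce a sequenced read to its Tn5 cut site (width-1 interval).

    Forward-strand reads are shifted +5 bp from their 5' end, reverse-strand
    reads -4 bp (i.e. cut position = end - 4).  The cut site may fall outside
    the read span for very short reads; only the 5' end matters.
    """
    if read.strand == "+":
        c = read.start + 5
    elif read.strand == "-":
        c = read.end - 4
    else:
        raise ValueError("cut site undefined for unstranded read")
    return GenomicInterval(read.chrom, c, c + 1, read.strand, read.name)


def split_at_summits(peak: GenomicInterval) -> list[GenomicInterval]:
    """Split a multi-summit peak into one sub-peak per summit.

    Boundaries fall at ``floor((s_i + s_{i+1}) / 2)``, assigned to the left
    sub-peak's exclusive end, so the k sub-peaks exactly tile
    ``[start, end)`` and each contains exactly one original summit.  For
    base-adjacent summits the boundary is clamped to ``s_i + 1`` so no
    sub-peak degenerates to zero width.  Names are suffixed ``_s1 .. _sk``
    in left-to-right order.
    """
    if not peak.summits:
        raise ValueError(f"peak {peak.name or peak} has no summits")
    s = peak.summits
    bounds = [peak.start]
    bounds += [max(int(math.floor((a + b) / 2)), a + 1) for a, b in zip(s, s[1:])]
    bounds.append(peak.end)
    base = peak.name or f"{peak.chrom}:{peak.start}-{peak.end}"
    out = []
    for i, (lo, hi) in enumerate(zip(bounds, bounds[1:])):
        out.append(
            GenomicInterval(
                peak.chrom, lo, hi, peak.strand,
                base if len(s) == 1 else f"{base}_s{i + 1}",
                peak.score, (s[i],),
            )
        )
    return out


def overlap_pairs(a: PeakSet, b: PeakSet) -> list[tuple[str, str]]:
    """All (a_id, b_id) pairs of intervals sharing >= 1 bp (half-open).

    Sweep-line over start-sorted intervals per chromosome; adjacent
    half-open intervals ([0,10) vs [10,20)) do not overlap.
    """
    pairs: list[tuple[str, str]] = []
    for chrom in a.chroms():
        bc = b.chrom_arrays(chrom)
        if bc is None:
            continue
        ac = a.chrom_arrays(chrom)
        b_start, b_end, b_name = bc["start"], bc["end"], bc["name"]
        j = 0
        active: list[int] = []
        for a_start, a_end, a_name in zip(ac["start"], ac["end"], ac["name"]):
            while j < len(b_start) and b_start[j] < a_end:
                active.append(j)
                j += 1
            # b's ending at or before this a's start can never overlap later
            # a's either (a starts are non-decreasing)
            active = [k for k in active if b_end[k] > a_start]
            for k in active:
                if b_start[k] < a_end:
                    pairs.append((a_name, b_name[k]))
    return pairs


def _point_distance(peak: GenomicInterval, pos: int) -> int:
    """Distance from a point to the peak: 0 inside, else gap to nearest edge."""
    if peak.start <= pos < peak.end:
        return 0
    if pos < peak.start:
        return peak.start - pos
    return pos - peak.end


def nearest_tss(
    peak: GenomicInterval, tss: PeakSet
) -> tuple[str | None, float]:
    """Nearest TSS (width-1 point) to a peak.

    Returns ``(gene_id, distance_bp)``.  Distance is 0 when the TSS lies
    inside the peak, otherwise the gap between the TSS position and the
    nearest peak edge coordinate.  Ties are broken by the smaller TSS
    coordinate.  With no TSS on the peak's chromosome the distance is
    ``+inf`` and the gene is ``None``.
    """
    arr = tss.chrom_arrays(peak.chrom)
    if arr is None or len(arr["start"]) == 0:
        return None, math.inf
    pos = arr["start"]
    inside = (pos >= peak.start) & (pos < peak.end)
    dist = np.where(
        inside, 0, np.where(pos < peak.start, peak.start - pos, pos - peak.end)
    )
    # positions are sorted ascending, so argmin returns the smallest
    # coordinate among ties
    i = int(np.argmin(dist))
    return str(arr["name"][i]), float(dist[i])


def classify_peak(
    peak: GenomicInterval,
    h3k27ac_peaks: PeakSet,
    h3k4me3_peaks: PeakSet,
    tss: PeakSet,
    radius_bp: int = 2000,
) -> PeakClass:
    """Assign an operational enhancer/promoter/unknown class to one peak.

    Promoter: the peak overlaps an H3K4me3 peak that itself overlaps a TSS.
    Enhancer: the peak overlaps an H3K27ac peak and its nearest TSS lies
    more than ``radius_bp`` away.  The promoter rule takes precedence.
    """
    gene, dist = nearest_tss(peak, tss)
    for k4 in h3k4me3_peaks.overlapping(peak):
        if tss.overlapping(k4):
            return PeakClass(peak.name or "", "promoter", gene, dist)
    if h3k27ac_peaks.overlapping(peak) and dist > radius_bp:
        return PeakClass(peak.name or "", "enhancer", gene, dist)
    return PeakClass(peak.name or "", "unknown", gene, dist)


def classify_peaks(
    peaks: PeakSet,
    h3k27ac_peaks: PeakSet,
    h3k4me3_peaks: PeakSet,
    tss: PeakSet,
    radius_bp: int = 2000,
) -> list[PeakClass]:
    """:func:`classify_peak` applied to every peak of a set (sorted order)."""
    return [
        classify_peak(p, h3k27ac_peaks, h3k4me3_peaks, tss, radius_bp)
        for p in peaks
    ]


def promoter_gene_map(
    peaks: PeakSet,
    h3k4me3_peaks: PeakSet,
    tss: PeakSet,
) -> dict[str, list[str]]:
    """Genes whose TSS is covered by an H3K4me3 peak overlapping each peak.

    Only peaks with at least one such gene appear in the mapping; these are
    exactly the peaks the promoter classification rule accepts.
    """
    out: dict[str, list[str]] = {}
    for p in peaks:
        genes: set[str] = set()
        for k4 in h3k4me3_peaks.overlapping(p):
            for t in tss.overlapping(k4):
                genes.add(t.name)
        if genes:
            out[p.name] = sorted(genes)
    return out


# ---------------------------------------------------------------------------
# BED-family I/O
# ---------------------------------------------------------------------------

def read_bed(path) -> PeakSet:
    """Read a 3-6 column BED file into a :class:`PeakSet`."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    ivs = []
    for row in df.itertuples(index=False):
        name = row[3] if len(row) > 3 and row[3] not in (None, ".") else None
        score = float(row[4]) if len(row) > 4 and row[4] not in (None, ".") else None
        strand = row[5] if len(row) > 5 and row[5] in _VALID_STRANDS else "."
        ivs.append(
            GenomicInterval(str(row[0]), int(row[1]), int(row[2]), strand, name, score)
        )
    return PeakSet(ivs)


def read_narrowpeak(path) -> PeakSet:
    """Read a 10-column narrowPeak file; column 10 is the summit offset
    from ``start`` (-1 means absent)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 10:
        raise ValueError("narrowPeak requires 10 columns")
    ivs = []
    for row in df.itertuples(index=False):
        start = int(row[1])
        offset = int(row[9])
        summits = (start + offset,) if offset >= 0 else None
        strand = row[5] if row[5] in _VALID_STRANDS else "."
        ivs.append(
            GenomicInterval(
                str(row[0]), start, int(row[2]), strand,
                None if row[3] == "." else str(row[3]),
                None if row[4] == "." else float(row[4]),
                summits,
            )
        )
    return PeakSet(ivs)


def read_tss_bed(path) -> PeakSet:
    """Read a BED of width-1 TSS points named by gene id."""
    ps = read_bed(path)
    bad = [iv.name for iv in ps if iv.width != 1]
    if bad:
        raise ValueError(f"TSS intervals must have width 1; offending: {bad[:5]}")
    return ps


def write_bed(peaks: PeakSet | Sequence[GenomicInterval], path) -> None:
    """Write intervals as BED6 (name '.' if absent, score 0 if absent)."""
    with open(path, "w") as fh:
        for iv in peaks:
            score = 0 if iv.score is None else iv.score
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}"
                f"\t{score:g}\t{iv.strand}\n"
            )


def write_narrowpeak(peaks: PeakSet | Sequence[GenomicInterval], path) -> None:
    """Write intervals as 10-column narrowPeak (first summit only)."""
    with open(path, "w") as fh:
        for iv in peaks:
            score = 0 if iv.score is None else iv.score
            offset = iv.summits[0] - iv.start if iv.summits else -1
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}"
                f"\t{score:g}\t{iv.strand}\t0\t-1\t-1\t{offset}\n"
            )
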