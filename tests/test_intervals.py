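import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metachrom.intervals import (
    GenomicInterval,
    PeakSet,
    classify_peak,
    classify_peaks,
    nearest_tss,
    overlap_pairs,
    read_narrowpeak,
    shift_tn5,
    split_at_summits,
    write_narrowpeak,
)


def iv(chrom, start, end, strand=".", name=None, summits=None):
    return GenomicInterval(chrom, start, end, strand, name, None, summits)


class TestGenomicInterval:
    def test_rejects_bad_coordinates(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)

    def test_rejects_bad_summits(self):
        with pytest.raises(ValueError):
            iv("chr1", 0, 100, summits=(150,))
        with pytest.raises(ValueError):
            iv("chr1", 0, 100, summits=(50, 50))

    def test_peakset_requires_unique_names(self):
        with pytest.raises(ValueError, match="duplicate"):
            PeakSet([iv("chr1", 0, 10, name="a"), iv("chr1", 20, 30, name="a")])


class TestShiftTn5:
    @pytest.mark.parametrize(
        "start,end,strand,expected",
        [
            (100, 150, "+", 105),  # forward 5' end + 5
            (100, 150, "-", 146),  # reverse 5' end (end) - 4
            (0, 3, "+", 5),  # offset applies to the 5' end even past read end
        ],
    )
    def test_cut_positions(self, start, end, strand, expected):
        cut = shift_tn5(iv("chr1", start, end, strand))
        assert (cut.start, cut.end) == (expected, expected + 1)
        assert cut.chrom == "chr1"

    def test_unstranded_is_an_error(self):
        with pytest.raises(ValueError):
            shift_tn5(iv("chr1", 100, 150, "."))


class TestSplitAtSummits:
    @pytest.mark.parametrize(
        "span,summits,expected",
        [
            ((0, 1000), (200, 700), [(0, 450), (450, 1000)]),
            ((0, 1000), (500,), [(0, 1000)]),
            ((10, 100), (20, 40, 80), [(10, 30), (30, 60), (60, 100)]),
        ],
    )
    def test_midpoint_boundaries(self, span, summits, expected):
        parts = split_at_summits(iv("chr1", *span, name="p", summits=summits))
        assert [(p.start, p.end) for p in parts] == expected
        for p, s in zip(parts, summits):
            assert p.summits == (s,)

    def test_no_summits_is_an_error(self):
        with pytest.raises(ValueError):
            split_at_summits(iv("chr1", 0, 100))

    def test_names_deterministic(self):
        parts = split_at_summits(iv("chr1", 0, 100, name="pk", summits=(10, 90)))
        assert [p.name for p in parts] == ["pk_s1", "pk_s2"]

    @given(
        start=st.integers(0, 1000),
        width=st.integers(2, 500),
        data=st.data(),
    )
    @settings(max_examples=200, deadline=None)
    def test_subpeaks_tile_input_exactly(self, start, width, data):
        end = start + width
        k = data.draw(st.integers(1, min(8, width)))
        summits = tuple(
            sorted(
                data.draw(
                    st.sets(st.integers(start, end - 1), min_size=k, max_size=k)
                )
            )
        )
        parts = split_at_summits(iv("chr1", start, end, summits=summits))
        assert parts[0].start == start and parts[-1].end == end
        for a, b in zip(parts, parts[1:]):
            assert a.end == b.start  # contiguous, disjoint
        assert sum(p.width for p in parts) == width
        for p, s in zip(parts, summits):
            assert p.start <= s < p.end  # one original summit each


def brute_force_pairs(a, b):
    return sorted(
        (x.name, y.name) for x in a for y in b if x.overlaps(y)
    )


class TestOverlapPairs:
    def test_basic_overlap(self):
        a = PeakSet([iv("chr1", 0, 10, name="a1")])
        b = PeakSet([iv("chr1", 5, 15, name="b1")])
        assert overlap_pairs(a, b) == [("a1", "b1")]

    def test_half_open_boundary(self):
        a = PeakSet([iv("chr1", 0, 10, name="a1")])
        b = PeakSet([iv("chr1", 10, 20, name="b1")])
        assert overlap_pairs(a, b) == []

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_random_sets(self, seed):
        rng = np.random.default_rng(seed)
        def random_set(prefix, n):
            ivs = []
            for i in range(n):
                chrom = f"chr{rng.integers(1, 4)}"
                s = int(rng.integers(0, 5000))
                ivs.append(iv(chrom, s, s + int(rng.integers(1, 300)),
                              name=f"{prefix}{i}"))
            return PeakSet(ivs)
        a, b = random_set("a", 200), random_set("b", 200)
        assert sorted(overlap_pairs(a, b)) == brute_force_pairs(a, b)


class TestNearestTss:
    tss = PeakSet([
        iv("chr1", 5000, 5001, "+", "gA"),
        iv("chr1", 6100, 6101, "+", "gB"),
    ])

    def test_gap_distance(self):
        tss = PeakSet([iv("chr1", 5000, 5001, "+", "gA")])
        gene, d = nearest_tss(iv("chr1", 6000, 6500), tss)
        assert (gene, d) == ("gA", 1000)

    def test_inside_peak_is_zero(self):
        gene, d = nearest_tss(iv("chr1", 6000, 6500), self.tss)
        assert (gene, d) == ("gB", 0)

    def test_tie_broken_by_smaller_coordinate(self):
        tss = PeakSet([
            iv("chr1", 5999, 6000, "+", "left"),
            iv("chr1", 6501, 6502, "+", "right"),
        ])
        gene, d = nearest_tss(iv("chr1", 6000, 6500), tss)
        assert (gene, d) == ("left", 1)

    def test_no_tss_on_chromosome(self):
        gene, d = nearest_tss(iv("chr9", 0, 100), self.tss)
        assert gene is None and math.isinf(d)

    def test_distance_symmetric_under_mirroring(self):
        # mirroring maps peak [s, e) -> [L - e, L - s) and the TSS marker
        # position p -> L - p, so edge distances are preserved
        L = 100_000
        rng = np.random.default_rng(3)
        pos = sorted(int(p) for p in rng.choice(range(1, L - 1), 20, replace=False))
        tss = PeakSet([iv("chr1", p, p + 1, "+", f"g{i}")
                       for i, p in enumerate(pos)])
        tss_m = PeakSet([iv("chr1", L - p, L - p + 1, "+", f"g{i}")
                         for i, p in enumerate(pos)])
        for s in rng.integers(0, L - 600, 30):
            peak = iv("chr1", int(s), int(s) + 500)
            mirrored = iv("chr1", L - peak.end, L - peak.start)
            assert nearest_tss(peak, tss)[1] == nearest_tss(mirrored, tss_m)[1]


class TestClassifyPeak:
    tss = PeakSet([iv("chr1", 1000, 1001, "+", "gA")])
    k4 = PeakSet([iv("chr1", 900, 1200, name="k4")])
    k27 = PeakSet([iv("chr1", 9500, 10500, name="k27")])

    def test_enhancer_far_from_tss(self):
        # overlaps H3K27ac, nearest TSS 2500 bp away -> enhancer
        tss = PeakSet([iv("chr1", 7500, 7501, "+", "gA")])
        pc = classify_peak(iv("chr1", 10000, 10400, name="p"), self.k27,
                           self.k4, tss)
        assert pc.cls == "enhancer" and pc.tss_distance == 2500

    def test_promoter_via_h3k4me3_with_tss(self):
        pc = classify_peak(iv("chr1", 950, 1300, name="p"), self.k27,
                           self.k4, self.tss)
        assert pc.cls == "promoter"

    def test_no_marks_is_unknown(self):
        pc = classify_peak(iv("chr1", 50000, 50400, name="p"), self.k27,
                           self.k4, self.tss)
        assert pc.cls == "unknown"

    def test_enhancer_within_radius_is_not_enhancer(self):
        tss = PeakSet([iv("chr1", 9000, 9001, "+", "gA")])
        pc = classify_peak(iv("chr1", 10000, 10400, name="p"), self.k27,
                           self.k4, tss)
        assert pc.cls == "unknown" and pc.tss_distance == 1000

    def test_promoter_takes_precedence(self):
        # satisfies both rules (K4me3+TSS overlap and K27ac + far TSS is
        # impossible simultaneously, so construct overlap of both marks)
        k4 = PeakSet([iv("chr1", 900, 1200, name="k4")])
        k27 = PeakSet([iv("chr1", 900, 1200, name="k27")])
        tss = PeakSet([iv("chr1", 1000, 1001, "+", "gA")])
        pc = classify_peak(iv("chr1", 950, 1300, name="p"), k27, k4, tss)
        assert pc.cls == "promoter"

    def test_total_and_deterministic(self, genome_small):
        classes = classify_peaks(
            genome_small["peaks"], genome_small["h3k27ac"],
            genome_small["h3k4me3"], genome_small["tss"],
        )
        assert len(classes) == len(genome_small["peaks"])
        assert all(c.cls in ("enhancer", "promoter", "unknown") for c in classes)


class TestNarrowPeakIO:
    def test_roundtrip_with_summit_offset(self, tmp_path):
        peaks = [
            iv("chr1", 100, 600, name="p1", summits=(250,)),
            iv("chr2", 0, 50, name="p2"),
        ]
        path = tmp_path / "x.narrowPeak"
        write_narrowpeak(peaks, path)
        back = read_narrowpeak(path)
        assert back["p1"].summits == (250,)
        assert back["p2"].summits is None
        assert (back["p1"].start, back["p1"].end) == (100, 600)
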