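"""Annotation hierarchy, 3'-exon geometry, auxiliary flags, saturation."""

import numpy as np
import pytest

from conftest import make_peak, make_transcript
from tagseq3.annotation import (
    CATEGORIES,
    AnnotationIndex,
    AnnotationParams,
    annotate_auxiliary,
    annotate_peaks,
    category_counts,
    classify_peak,
    detection_saturation,
    distance_to_3prime,
    is_3prime_exon,
)


def classify(peak, transcripts, params=None):
    return classify_peak(peak, AnnotationIndex(transcripts, params))


def brute_force_category(peak, transcripts, flank=5000):
    """All-pairs overlap oracle, written independently of the interval index."""
    def ov(a_start, a_end, b_start, b_end):
        return min(a_end, b_end) > max(a_start, b_start)

    exon_hits = [
        t
        for t in transcripts
        if t.chrom == peak.chrom and any(ov(peak.start, peak.end, s, e) for s, e in t.exons)
    ]
    if any(t.is_coding for t in exon_hits):
        return "coding_exon"
    if any(t.is_lncrna for t in exon_hits):
        return "lncrna"
    if exon_hits:
        return "exon_other"
    if any(
        t.chrom == peak.chrom and ov(peak.start, peak.end, t.start, t.end)
        for t in transcripts
    ):
        return "intron"
    promoter = downstream = False
    for t in transcripts:
        if t.chrom != peak.chrom:
            continue
        if t.strand == "+":
            pr, dn = (t.start - flank, t.start), (t.end, t.end + flank)
        else:
            pr, dn = (t.end, t.end + flank), (t.start - flank, t.start)
        promoter |= ov(peak.start, peak.end, *pr)
        downstream |= ov(peak.start, peak.end, *dn)
    if promoter:
        return "promoter_flank"
    if downstream:
        return "downstream_flank"
    return "intergenic"


class TestClassifyPeak:
    def test_peak_inside_coding_exon(self):
        t = make_transcript(exons=[(1000, 2000)], is_coding=True)
        assert classify(make_peak(start=1200, end=1300), [t]) == "coding_exon"

    def test_lncrna_after_coding_exclusion(self):
        lnc = make_transcript("lnc", exons=[(1000, 2000)], is_coding=False)
        assert classify(make_peak(start=1200, end=1300), [lnc]) == "lncrna"

    def test_coding_beats_lncrna(self):
        lnc = make_transcript("lnc", exons=[(1000, 2000)], is_coding=False)
        cod = make_transcript("cod", exons=[(1100, 1400)], is_coding=True)
        assert classify(make_peak(start=1200, end=1300), [lnc, cod]) == "coding_exon"

    def test_intron(self):
        t = make_transcript(exons=[(1000, 1100), (9000, 9500)])
        assert classify(make_peak(start=4000, end=4100), [t]) == "intron"

    def test_flanks_are_strand_aware(self):
        t = make_transcript(exons=[(10_000, 12_000)], strand="-")
        # - strand: promoter side is past the genomic end
        assert classify(make_peak(start=13_000, end=13_100), [t]) == "promoter_flank"
        assert classify(make_peak(start=6_000, end=6_100), [t]) == "downstream_flank"

    def test_intergenic_beyond_5kb(self):
        t = make_transcript(exons=[(1000, 2000)])
        assert classify(make_peak(start=8000, end=8100), [t]) == "intergenic"
        assert classify(make_peak(start=6999, end=7100), [t]) == "downstream_flank"

    def test_overlap_is_strand_agnostic(self):
        t = make_transcript(exons=[(1000, 2000)], strand="+", is_coding=True)
        assert classify(make_peak(strand="-", start=1500, end=1600), [t]) == "coding_exon"

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        transcripts = []
        for i in range(40):
            start = int(rng.integers(0, 200_000))
            n_ex = int(rng.integers(1, 4))
            bounds = np.sort(rng.integers(0, 3000, size=2 * n_ex - 1))
            exons, cur = [], start
            for k in range(n_ex):
                length = int(rng.integers(100, 800))
                exons.append((cur, cur + length))
                cur += length + int(rng.integers(200, 1000))
            transcripts.append(
                make_transcript(
                    f"t{i}",
                    strand="+" if rng.random() < 0.5 else "-",
                    exons=exons,
                    is_coding=bool(rng.random() < 0.4),
                    source="lncRNA-catalog-1" if rng.random() < 0.5 else "all_mrna-like",
                )
            )
        index = AnnotationIndex(transcripts)
        for j in range(200):
            s = int(rng.integers(0, 210_000))
            peak = make_peak(f"p{j}", start=s, end=s + int(rng.integers(50, 400)))
            assert classify_peak(peak, index) == brute_force_category(peak, transcripts)

    def test_annotation_order_invariant(self):
        rng = np.random.default_rng(1)
        ts = [
            make_transcript(f"t{i}", exons=[(i * 3000, i * 3000 + 500)],
                            is_coding=bool(i % 2))
            for i in range(10)
        ]
        peak = make_peak(start=9100, end=9200)
        assert classify(peak, ts) == classify(peak, ts[::-1])

    def test_every_peak_gets_one_category_and_counts_sum(self):
        ts = [make_transcript(exons=[(1000, 2000)])]
        peaks = [make_peak(f"p{i}", start=1000 + 4000 * i, end=1100 + 4000 * i)
                 for i in range(5)]
        anns = annotate_peaks(peaks, ts)
        counts = category_counts(anns)
        assert set(counts) == set(CATEGORIES)
        assert sum(counts.values()) == len(peaks)


class TestThreePrimeExon:
    def test_last_exon_plus_strand(self):
        t = make_transcript(exons=[(1000, 1200), (5000, 6000)], strand="+")
        assert is_3prime_exon(make_peak(start=5500, end=5600), t)
        assert not is_3prime_exon(make_peak(start=1050, end=1100), t)

    def test_last_exon_minus_strand_is_lowest(self):
        t = make_transcript(exons=[(1000, 1200), (5000, 6000)], strand="-")
        assert is_3prime_exon(make_peak(start=1050, end=1100), t)
        assert not is_3prime_exon(make_peak(start=5500, end=5600), t)

    def test_single_exon_any_overlap(self):
        t = make_transcript(exons=[(1000, 2000)], strand="+")
        assert is_3prime_exon(make_peak(start=1500, end=1600), t)


class TestDistanceTo3Prime:
    def test_worked_plus_strand_example(self):
        t = make_transcript(exons=[(2000, 10_000)], strand="+")
        peak = make_peak(start=9700, end=9725)
        assert distance_to_3prime(peak, [t]) == 275

    def test_zero_at_the_end(self):
        t = make_transcript(exons=[(2000, 10_000)], strand="+")
        assert distance_to_3prime(make_peak(start=9900, end=10_000), [t]) == 0

    def test_minus_strand_mirror(self):
        t = make_transcript(exons=[(2000, 10_000)], strand="-")
        peak = make_peak(strand="-", start=2275, end=2300)
        assert distance_to_3prime(peak, [t]) == 275

    def test_nearest_by_absolute_distance(self):
        near = make_transcript("near", exons=[(1000, 9_500)], strand="+")
        far = make_transcript("far", exons=[(20_000, 30_000)], strand="+")
        assert distance_to_3prime(make_peak(start=9700, end=9725), [near, far]) == -225

    def test_undefined_without_same_strand_transcript(self):
        t = make_transcript(exons=[(2000, 10_000)], strand="-")
        assert distance_to_3prime(make_peak(strand="+", start=9700, end=9725), [t]) is None


class TestAuxiliaryFlags:
    def test_repeat_overlap(self):
        flags = annotate_auxiliary(make_peak(start=100, end=200),
                                   {"repeat": [("chr1", 150, 300)]})
        assert flags == {"repeat"}

    def test_no_overlaps_empty(self):
        flags = annotate_auxiliary(make_peak(start=100, end=200),
                                   {"repeat": [("chr2", 150, 300)]})
        assert flags == set()

    def test_mirrored_peaks_flag_each_other_antisense(self):
        a = make_peak("a", strand="+", start=100, end=200)
        b = make_peak("b", strand="-", start=100, end=200)
        assert "antisense_to_peak" in annotate_auxiliary(a, {}, [a, b])
        assert "antisense_to_peak" in annotate_auxiliary(b, {}, [a, b])

    def test_stranded_track_prefix_convention(self):
        peak = make_peak(strand="+", start=100, end=200)
        tracks = {"antisense_gencode": [("chr1", 150, 300, "+")],
                  "sense_gencode": [("chr1", 150, 300, "+")]}
        flags = annotate_auxiliary(peak, tracks)
        assert flags == {"sense_gencode"}


class TestDetectionSaturation:
    def _reads(self, transcripts, per_transcript=10):
        reads = []
        for t in transcripts:
            mid = (t.start + t.end) // 2
            reads += [(t.chrom, t.strand, mid + i) for i in range(per_transcript)]
        return reads

    def test_full_fraction_equals_direct_tally(self):
        ts = [make_transcript(f"t{i}", exons=[(i * 10_000, i * 10_000 + 2000)])
              for i in range(5)]
        reads = self._reads(ts)
        curve = detection_saturation(reads, ts, [1.0], seed=0)
        assert curve == [(len(reads), 5)]

    def test_zero_fraction_detects_nothing(self):
        ts = [make_transcript(exons=[(0, 2000)])]
        assert detection_saturation(self._reads(ts), ts, [0.0], seed=0) == [(0, 0)]

    def test_monotone_and_saturating(self):
        ts = [make_transcript(f"t{i}", exons=[(i * 10_000, i * 10_000 + 2000)])
              for i in range(8)]
        reads = self._reads(ts, per_transcript=10)
        curve = detection_saturation(reads, ts, [0.1, 0.25, 0.5, 0.75, 1.0], seed=1)
        counts = [c for _, c in curve]
        assert counts == sorted(counts)
        assert counts[-1] == 8
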