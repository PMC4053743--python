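"""Classification of tag-cluster peaks against transcript annotation.

Each peak receives exactly one category from a fixed priority hierarchy:

1. ``coding_exon``    — overlaps an exon of an annotated coding gene
2. ``lncrna``         — overlaps an exon of a catalogued lncRNA (after the
                        coding exclusion)
3. ``exon_other``     — overlaps an exon of any other known transcript
4. ``intron``         — inside a transcript span without touching an exon
5. ``promoter_flank`` / ``downstream_flank`` — within 5 kb of a transcript
                        5' or 3' end (strand-aware)
6. ``intergenic``     — more than 5 kb from every known transcript; the
                        candidate novel-transcript class

Overlap means at least one shared base on genomic coordinates and is
strand-agnostic by default (sense/antisense relationships are recorded as
auxiliary flags instead); exonic classes are decided at the exon level, not
the transcript span.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

__all__ = [
    "TranscriptModel",
    "AnnotationParams",
    "PeakAnnotation",
    "AnnotationIndex",
    "classify_peak",
    "is_3prime_exon",
    "distance_to_3prime",
    "annotate_auxiliary",
    "annotate_peaks",
    "category_counts",
    "detection_saturation",
    "CATEGORIES",
]

CATEGORIES = (
    "coding_exon",
    "lncrna",
    "exon_other",
    "intron",
    "promoter_flank",
    "downstream_flank",
    "intergenic",
)

LNCRNA_SOURCES_PREFIX = "lncRNA-catalog"


@dataclass
class TranscriptModel:
    """A stranded, exon-structured annotation entry.

    exons are 0-based half-open intervals, sorted and non-overlapping.
    ``source`` tags the catalog of origin (refseq-like, ucsc-like,
    gencode-like, lncRNA-catalog-1..4, all_mrna-like, ...).
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    is_coding: bool = False
    source: str = "refseq-like"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: at least one exon required")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: bad strand {self.strand!r}")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        if any(s >= e for s, e in self.exons):
            raise ValueError(f"{self.transcript_id}: empty exon")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def is_lncrna(self) -> bool:
        return self.source.startswith(LNCRNA_SOURCES_PREFIX)

    @property
    def three_prime(self) -> int:
        """Half-open boundary coordinate of the 3' end (strand-aware)."""
        return self.end if self.strand == "+" else self.start

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def last_exon(self) -> tuple[int, int]:
        """Strand-aware 3'-most exon."""
        return self.exons[-1] if self.strand == "+" else self.exons[0]


@dataclass(frozen=True)
class AnnotationParams:
    flank: int = 5000
    min_overlap: int = 1

    def __post_init__(self) -> None:
        if self.flank < 0:
            raise ValueError("flank must be >= 0")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")


@dataclass
class PeakAnnotation:
    """One peak's classification result."""

    peak_id: str
    category: str
    in_3prime_exon: bool = False
    distance_to_3prime: float | None = None  # signed bp, upstream positive
    aux_flags: set = field(default_factory=set)


class AnnotationIndex:
    """Interval-tree indexes over a transcript set for fast peak queries."""

    def __init__(self, transcripts: Sequence[TranscriptModel], params: AnnotationParams | None = None):
        self.params = params or AnnotationParams()
        self.transcripts = list(transcripts)
        self._exons: dict[str, IntervalTree] = {}
        self._spans: dict[str, IntervalTree] = {}
        for t in self.transcripts:
            spans = self._spans.setdefault(t.chrom, IntervalTree())
            spans.addi(t.start, t.end, t)
            exons = self._exons.setdefault(t.chrom, IntervalTree())
            for s, e in t.exons:
                exons.addi(s, e, t)

    def exon_hits(self, chrom: str, start: int, end: int) -> list[TranscriptModel]:
        tree = self._exons.get(chrom)
        if tree is None:
            return []
        min_ov = self.params.min_overlap
        out = []
        for iv in tree.overlap(start, end):
            if min(iv.end, end) - max(iv.begin, start) >= min_ov:
                out.append(iv.data)
        return out

    def span_hits(self, chrom: str, start: int, end: int) -> list[TranscriptModel]:
        tree = self._spans.get(chrom)
        if tree is None:
            return []
        min_ov = self.params.min_overlap
        return [
            iv.data
            for iv in tree.overlap(start, end)
            if min(iv.end, end) - max(iv.begin, start) >= min_ov
        ]


def _flank_hit(peak, t: TranscriptModel, flank: int) -> str | None:
    """'promoter' / 'downstream' if the peak lies within flank bp of the
    transcript 5' / 3' end on the respective side, else None."""
    if t.strand == "+":
        promoter = (t.start - flank, t.start)
        downstream = (t.end, t.end + flank)
    else:
        promoter = (t.end, t.end + flank)
        downstream = (t.start - flank, t.start)
    if min(promoter[1], peak.end) > max(promoter[0], peak.start):
        return "promoter"
    if min(downstream[1], peak.end) > max(downstream[0], peak.start):
        return "downstream"
    return None


def classify_peak(peak, index: AnnotationIndex) -> str:
    """Assign the single highest-priority category to a peak."""
    params = index.params
    exon_hits = index.exon_hits(peak.chrom, peak.start, peak.end)
    if any(t.is_coding for t in exon_hits):
        return "coding_exon"
    if any(t.is_lncrna for t in exon_hits):
        return "lncrna"
    if exon_hits:
        return "exon_other"
    if index.span_hits(peak.chrom, peak.start, peak.end):
        return "intron"
    flanks = set()
    tree = index._spans.get(peak.chrom)
    if tree is not None:
        for iv in tree.overlap(peak.start - params.flank, peak.end + params.flank):
            hit = _flank_hit(peak, iv.data, params.flank)
            if hit:
                flanks.add(hit)
    if "promoter" in flanks:
        return "promoter_flank"
    if "downstream" in flanks:
        return "downstream_flank"
    return "intergenic"


def is_3prime_exon(peak, transcript: TranscriptModel) -> bool:
    """True iff the peak overlaps the transcript's strand-aware last exon."""
    if peak.chrom != transcript.chrom:
        return False
    s, e = transcript.last_exon
    return min(e, peak.end) > max(s, peak.start)


def distance_to_3prime(peak, transcripts: Iterable[TranscriptModel]) -> float | None:
    """Signed genomic distance from the peak's 3' boundary to the nearest
    same-strand transcript 3' end; upstream positive, None when no
    same-strand transcript exists on the peak's chromosome.

    Distances are between half-open boundary coordinates, so a peak whose 3'
    edge abuts the transcript 3' end scores 0.
    """
    best: float | None = None
    peak_3p = peak.end if peak.strand == "+" else peak.start
    for t in transcripts:
        if t.chrom != peak.chrom or t.strand != peak.strand:
            continue
        if peak.strand == "+":
            d = t.three_prime - peak_3p
        else:
            d = peak_3p - t.three_prime
        if best is None or abs(d) < abs(best):
            best = float(d)
    return best


def annotate_auxiliary(
    peak,
    aux_tracks: Mapping[str, Sequence[tuple]],
    all_peaks: Sequence = (),
) -> set:
    """Flag overlaps with auxiliary tracks plus antisense 3'-tag peaks.

    aux_tracks maps a flag name (conserved, repeat, est, spliced_est,
    pseudogene, rrna_pseudogene, ...) to intervals (chrom, start, end) or
    (chrom, start, end, strand); stranded track names may use the
    sense_/antisense_ prefix convention to require a strand relationship.
    """
    flags: set = set()
    for name, intervals in aux_tracks.items():
        for iv in intervals:
            chrom, start, end = iv[0], iv[1], iv[2]
            if chrom != peak.chrom or min(end, peak.end) <= max(start, peak.start):
                continue
            if len(iv) >= 4 and iv[3] in "+-":
                same = iv[3] == peak.strand
                if name.startswith("antisense_") and same:
                    continue
                if name.startswith("sense_") and not same:
                    continue
            flags.add(name)
            break
    for other in all_peaks:
        if (
            other is not peak
            and other.chrom == peak.chrom
            and other.strand != peak.strand
            and min(other.end, peak.end) > max(other.start, peak.start)
        ):
            flags.add("antisense_to_peak")
            break
    return flags


def annotate_peaks(
    peaks: Sequence,
    transcripts: Sequence[TranscriptModel],
    params: AnnotationParams | None = None,
    aux_tracks: Mapping[str, Sequence[tuple]] | None = None,
) -> list[PeakAnnotation]:
    """Classify every peak; one category each, 3'-exon flag and distance."""
    index = AnnotationIndex(transcripts, params)
    same_chrom: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        same_chrom.setdefault(t.chrom, []).append(t)
    out = []
    for peak in peaks:
        cat = classify_peak(peak, index)
        in3p = any(
            is_3prime_exon(peak, t) for t in index.exon_hits(peak.chrom, peak.start, peak.end)
        )
        dist = distance_to_3prime(peak, same_chrom.get(peak.chrom, ()))
        flags = annotate_auxiliary(peak, aux_tracks or {}, peaks)
        out.append(PeakAnnotation(peak.peak_id, cat, in3p, dist, flags))
    return out


def category_counts(annotations: Sequence[PeakAnnotation]) -> dict[str, int]:
    """Peak tally per category (always includes every category key)."""
    counts = {c: 0 for c in CATEGORIES}
    for a in annotations:
        counts[a.category] += 1
    return counts


def detection_saturation(
    reads: Sequence,
    transcripts: Sequence[TranscriptModel],
    subsample_fractions: Sequence[float],
    seed: int = 0,
) -> list[tuple[int, int]]:
    """Transcript-detection saturation curve for one sample.

    A transcript counts as detected when at least one read start falls within
    its span on its strand. Reads are shuffled once and each fraction takes a
    prefix, so the curve is monotone non-decreasing by construction and the
    full fraction equals the direct tally.

    ``reads`` are (chrom, strand, pos) triples or objects with those fields.
    Returns [(depth, n_detected), ...] sorted by depth.
    """
    if any(not 0.0 <= f <= 1.0 for f in subsample_fractions):
        raise ValueError("subsample fractions must be in [0, 1]")
    rng = np.random.default_rng(seed)

    def _fields(r):
        if isinstance(r, tuple):
            return r[0], r[1], r[2]
        return r.chrom, r.strand, r.pos

    order = rng.permutation(len(reads))
    index = AnnotationIndex(transcripts)
    curve = []
    for frac in sorted(subsample_fractions):
        depth = int(round(frac * len(reads)))
        detected = set()
        for i in order[:depth]:
            chrom, strand, pos = _fields(reads[int(i)])
            for t in index.span_hits(chrom, pos, pos + 1):
                if t.strand == strand:
                    detected.add(t.transcript_id)
        curve.append((depth, len(detected)))
    return curve
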