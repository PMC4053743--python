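"""Strand-specific peak calling from pooled 3'-tag read starts.

Reads from all samples are pooled and, per (chromosome, strand), read start
positions within ``merge_gap`` bp (default 20) of their nearest same-strand
neighbour are chained into clusters. A cluster's interval runs from its
left-most to its right-most read start (half-open). Clusters become peaks
when they hold strictly more than ``min_pooled_reads`` reads (default 150)
and at least ``min_unique_starts`` distinct start positions (default 25).
Peaks antisense to peaks inside known-gene exons are removed as library
artifacts, and a stricter ``strict_min_reads`` (default 200) cut yields the
final set. Fold enrichment compares observed counts with the expectation
under reads placed uniformly over the mappable genome.

Filter order is fixed: cluster -> pooled-read threshold -> unique-start
filter -> antisense-artifact removal -> strict threshold.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotation import TranscriptModel

__all__ = [
    "ReadStart",
    "Peak",
    "PeakCallParams",
    "cluster_read_starts",
    "call_peaks",
    "filter_antisense_artifacts",
    "apply_strict_threshold",
    "fold_enrichment",
    "call_and_filter",
]


@dataclass(frozen=True)
class ReadStart:
    """The 5'-most sequenced position of one tag in read orientation."""

    chrom: str
    strand: str
    pos: int
    sample: str = ""


@dataclass
class Peak:
    """A strand-specific cluster of read starts."""

    peak_id: str
    chrom: str
    strand: str
    start: int  # 0-based half-open over read starts
    end: int
    n_reads_pooled: int
    n_unique_starts: int
    per_sample_counts: dict[str, int] = field(default_factory=dict)
    fold_enrichment_pooled: float | None = None
    fold_enrichment_max_sample: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.peak_id}: empty interval")
        if self.n_unique_starts > self.n_reads_pooled:
            raise ValueError(f"{self.peak_id}: unique starts exceed read count")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PeakCallParams:
    merge_gap: int = 20
    min_pooled_reads: int = 150  # strict '>' threshold
    min_unique_starts: int = 25  # '>=' threshold
    strict_min_reads: int = 200  # '>=' threshold
    mappable_size: int = 2_700_000_000

    def __post_init__(self) -> None:
        if min(
            self.merge_gap,
            self.min_pooled_reads,
            self.min_unique_starts,
            self.strict_min_reads,
            self.mappable_size,
        ) <= 0:
            raise ValueError("all peak-calling parameters must be positive")


def cluster_read_starts(
    starts: Iterable[ReadStart], merge_gap: int = 20
) -> dict[tuple[str, str], list[list[ReadStart]]]:
    """Chain read starts into raw clusters per (chrom, strand).

    Consecutive sorted start positions at most ``merge_gap`` apart belong to
    one cluster; adjacent clusters are separated by more than ``merge_gap``.
    Input order and duplicates are irrelevant. Strands never merge.
    """
    grouped: dict[tuple[str, str], list[ReadStart]] = {}
    for r in starts:
        grouped.setdefault((r.chrom, r.strand), []).append(r)
    clusters: dict[tuple[str, str], list[list[ReadStart]]] = {}
    for key, reads in sorted(grouped.items()):
        reads.sort(key=lambda r: r.pos)
        out: list[list[ReadStart]] = []
        current: list[ReadStart] = [reads[0]]
        for r in reads[1:]:
            if r.pos - current[-1].pos <= merge_gap:
                current.append(r)
            else:
                out.append(current)
                current = [r]
        out.append(current)
        clusters[key] = out
    return clusters


def _cluster_to_peak(reads: list[ReadStart], peak_id: str) -> Peak:
    positions = [r.pos for r in reads]
    per_sample = Counter(r.sample for r in reads)
    return Peak(
        peak_id=peak_id,
        chrom=reads[0].chrom,
        strand=reads[0].strand,
        start=min(positions),
        end=max(positions) + 1,
        n_reads_pooled=len(reads),
        n_unique_starts=len(set(positions)),
        per_sample_counts=dict(per_sample),
    )


def call_peaks(
    starts: Iterable[ReadStart], params: PeakCallParams | None = None
) -> list[Peak]:
    """Call peaks from pooled (already posterior-filtered) read starts.

    Clusters must carry strictly more than ``min_pooled_reads`` reads and at
    least ``min_unique_starts`` distinct start positions, applied in that
    order. Peaks come back sorted by (chrom, start, strand) and numbered.
    """
    params = params or PeakCallParams()
    clusters = cluster_read_starts(starts, params.merge_gap)
    raw = [
        reads
        for per_key in clusters.values()
        for reads in per_key
        if len(reads) > params.min_pooled_reads
    ]
    raw = [reads for reads in raw if len({r.pos for r in reads}) >= params.min_unique_starts]
    raw.sort(key=lambda reads: (reads[0].chrom, min(r.pos for r in reads), reads[0].strand))
    return [_cluster_to_peak(reads, f"peak_{i + 1}") for i, reads in enumerate(raw)]


def _overlaps(a, b) -> bool:
    return a.chrom == b.chrom and min(a.end, b.end) > max(a.start, b.start)


def filter_antisense_artifacts(
    peaks: Sequence[Peak], coding_annotation: Sequence[TranscriptModel]
) -> tuple[list[Peak], list[Peak]]:
    """Remove peaks antisense to peaks inside known-gene exons.

    A peak is removed iff it overlaps (>= 1 bp, opposite strand) another
    called peak that itself overlaps an exon of a known gene on that gene's
    strand. Returns (retained, removed).
    """
    exonic_sense: list[Peak] = []
    for p in peaks:
        for t in coding_annotation:
            if t.chrom != p.chrom or t.strand != p.strand:
                continue
            if any(min(e, p.end) > max(s, p.start) for s, e in t.exons):
                exonic_sense.append(p)
                break
    retained, removed = [], []
    for p in peaks:
        artifact = any(
            q.strand != p.strand and _overlaps(p, q) for q in exonic_sense if q is not p
        )
        (removed if artifact else retained).append(p)
    return retained, removed


def apply_strict_threshold(peaks: Sequence[Peak], strict_min_reads: int = 200) -> list[Peak]:
    """Keep peaks with at least ``strict_min_reads`` pooled reads (idempotent)."""
    return [p for p in peaks if p.n_reads_pooled >= strict_min_reads]


def fold_enrichment(
    peak: Peak,
    total_reads: int,
    mappable_size: int,
    per_sample_totals: Mapping[str, int] | None = None,
) -> Peak:
    """Attach pooled and max-per-sample enrichment over a uniform background.

    expected = total_reads * peak_length / mappable_size;
    enrichment = observed / expected, pooled and per sample (the per-sample
    expectation uses that sample's library total).
    """
    if mappable_size <= 0:
        raise ValueError("mappable_size must be > 0")
    if peak.length <= 0:
        raise ValueError(f"{peak.peak_id}: zero-length peak")
    expected = total_reads * peak.length / mappable_size
    pooled = peak.n_reads_pooled / expected if expected > 0 else float("inf")
    max_sample = None
    if per_sample_totals:
        ratios = []
        for sample, n in peak.per_sample_counts.items():
            tot = per_sample_totals.get(sample, 0)
            if tot > 0:
                exp_s = tot * peak.length / mappable_size
                ratios.append(n / exp_s)
        max_sample = max(ratios) if ratios else None
    return replace(
        peak, fold_enrichment_pooled=pooled, fold_enrichment_max_sample=max_sample
    )


def call_and_filter(
    starts: Iterable[ReadStart],
    coding_annotation: Sequence[TranscriptModel] = (),
    params: PeakCallParams | None = None,
) -> dict:
    """Run the full peak-calling chain; returns every intermediate stage.

    Stages: 'initial' (cluster + count/uniqueness filters), 'retained' /
    'antisense_removed', and 'final' (strict threshold, enrichment attached).
    """
    params = params or PeakCallParams()
    starts = list(starts)
    initial = call_peaks(starts, params)
    retained, removed = filter_antisense_artifacts(initial, coding_annotation)
    final = apply_strict_threshold(retained, params.strict_min_reads)
    total = len(starts)
    per_sample_totals = Counter(r.sample for r in starts)
    final = [
        fold_enrichment(p, total, params.mappable_size, per_sample_totals) for p in final
    ]
    return {
        "initial": initial,
        "retained": retained,
        "antisense_removed": removed,
        "final": final,
    }
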