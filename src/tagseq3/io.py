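"""Readers and writers for the plain-text formats the pipeline exchanges.

Coordinates are 0-based half-open everywhere internally (the BED
convention). The read "start" of a - strand alignment is its genomic right
edge (the 5'-most sequenced base in read orientation).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

from .align_filter import AlignmentRecord, Candidate
from .annotation import TranscriptModel
from .peaks import Peak, ReadStart

__all__ = [
    "read_bed12",
    "read_gtf",
    "read_reads_bed",
    "write_kept_reads_bed",
    "read_sam_alignments",
    "read_aux_bed",
    "write_peaks_bed",
]


def read_bed12(path) -> list[TranscriptModel]:
    """BED12 transcripts; coding status inferred from a non-empty thick region."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{ln}: expected 12 BED columns, got {len(f)}")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            out.append(
                TranscriptModel(
                    transcript_id=name,
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                    is_coding=thick_end > thick_start,
                )
            )
    return out


def read_gtf(path, coding_biotypes: tuple[str, ...] = ("protein_coding",)) -> list[TranscriptModel]:
    """GTF exon records grouped into transcripts (via pyranges).

    A transcript is coding when it has CDS features or a coding biotype.
    """
    import pyranges as pr

    df = pr.read_gtf(path).df
    exon_rows = df[df["Feature"] == "exon"]
    cds_ids = set(df.loc[df["Feature"] == "CDS", "transcript_id"]) if "transcript_id" in df else set()
    out = []
    for tid, grp in exon_rows.groupby("transcript_id", sort=True):
        biotype = ""
        for col in ("transcript_biotype", "gene_biotype", "transcript_type", "gene_type"):
            if col in grp.columns:
                biotype = str(grp[col].iloc[0])
                break
        out.append(
            TranscriptModel(
                transcript_id=str(tid),
                chrom=str(grp["Chromosome"].iloc[0]),
                strand=str(grp["Strand"].iloc[0]),
                exons=[(int(s), int(e)) for s, e in zip(grp["Start"], grp["End"])],
                is_coding=tid in cds_ids or biotype in coding_biotypes,
                source="gtf",
            )
        )
    return out


def write_kept_reads_bed(kept: Sequence[tuple[str, Candidate]], read_length: int, path) -> None:
    """Write posterior-filtered reads (read_id, best candidate) as BED6."""
    with open(path, "w") as fh:
        for read_id, c in kept:
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.start + read_length}\t{read_id}\t"
                f"{c.mismatches}\t{c.strand}\n"
            )


def read_reads_bed(path, sample: str = "") -> list[ReadStart]:
    """Filtered-read BED -> read starts under the strand-aware convention."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{ln}: expected >= 6 BED columns")
            chrom, start, end, strand = f[0], int(f[1]), int(f[2]), f[5]
            pos = start if strand == "+" else end - 1
            out.append(ReadStart(chrom, strand, pos, sample))
    return out


def read_sam_alignments(path, read_length: int | None = None) -> list[AlignmentRecord]:
    """SAM with NM tags: one line per candidate alignment, grouped by name."""
    import pysam

    by_read: dict[str, list[Candidate]] = {}
    lengths: dict[str, int] = {}
    order: list[str] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            name = aln.query_name
            if name not in by_read:
                by_read[name] = []
                order.append(name)
                lengths[name] = read_length or aln.query_length or aln.infer_read_length()
            by_read[name].append(
                Candidate(
                    aln.reference_name,
                    aln.reference_start,
                    "-" if aln.is_reverse else "+",
                    int(aln.get_tag("NM")) if aln.has_tag("NM") else 0,
                )
            )
    return [AlignmentRecord(name, lengths[name], by_read[name]) for name in order]


def read_aux_bed(path) -> list[tuple]:
    """Auxiliary track BED -> (chrom, start, end[, strand]) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) >= 6 and f[5] in "+-":
                out.append((f[0], int(f[1]), int(f[2]), f[5]))
            else:
                out.append((f[0], int(f[1]), int(f[2])))
    return out


def write_peaks_bed(peaks: Sequence[Peak], path) -> None:
    """BED6+ peaks: name, pooled reads as score, strand, then extra columns
    (n_reads, n_unique_starts, pooled and max-sample enrichment)."""
    with open(path, "w") as fh:
        for p in peaks:
            fe = "" if p.fold_enrichment_pooled is None else f"{p.fold_enrichment_pooled:.4g}"
            fm = (
                ""
                if p.fold_enrichment_max_sample is None
                else f"{p.fold_enrichment_max_sample:.4g}"
            )
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t{p.n_reads_pooled}\t"
                f"{p.strand}\t{p.n_reads_pooled}\t{p.n_unique_starts}\t{fe}\t{fm}\n"
            )
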