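"""Synthetic 3'-tag sequencing cohorts with known ground truth.

The generator emulates the statistical structure of a 3'-end sequencing
(3SEQ) experiment: only the 3'-most polyadenylated fragment of each transcript
is sequenced, so reads pile up on the transcript strand in a tight cluster
whose 5' (sequencing-start) positions sit a few hundred bases upstream of the
transcript 3' end. On top of this signal sit uniformly placed background
reads on random strands, library-size variation between samples, and a
controllable fraction of multimapping reads carrying decoy alignments.

Reads are fixed at 25 bp, mirroring short single-end tag sequencing; per-read
mismatch counts stay within the two-mismatch alignment allowance. The read
"start" is the 5'-most sequenced position in read orientation: the leftmost
genomic base for + strand alignments and the rightmost for - strand
alignments. The fragment-offset model is a truncated normal (at zero)
distance upstream of the 3' end, mean 275 bp by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .align_filter import AlignmentRecord, Candidate
from .annotation import TranscriptModel

READ_LENGTH = 25  # bp, short single-end tag

__all__ = [
    "READ_LENGTH",
    "ToyGenome",
    "FragmentOffsetModel",
    "CohortDesign",
    "NovelLocus",
    "make_toy_annotation",
    "simulate_3seq_sample",
    "simulate_cohort",
    "read_start_position",
    "write_alignments_bed",
    "write_annotation_bed12",
    "write_truth_tsv",
]


@dataclass(frozen=True)
class ToyGenome:
    """A small multi-chromosome genome for simulation.

    mappable_size defaults to the full genome; it is the denominator of the
    uniform-background enrichment model downstream.
    """

    chrom_sizes: Mapping[str, int]
    mappable_size: int | None = None

    def __post_init__(self) -> None:
        if not self.chrom_sizes:
            raise ValueError("genome must contain at least one chromosome")
        if any(v <= 0 for v in self.chrom_sizes.values()):
            raise ValueError("all chromosome lengths must be > 0")
        total = sum(self.chrom_sizes.values())
        if self.mappable_size is None:
            object.__setattr__(self, "mappable_size", total)
        elif not 0 < self.mappable_size <= total:
            raise ValueError("mappable_size must be in (0, sum of chrom sizes]")

    @property
    def total_size(self) -> int:
        return sum(self.chrom_sizes.values())


@dataclass(frozen=True)
class FragmentOffsetModel:
    """Distance (bp) from a read's 5' start to the transcript 3' end.

    Truncated-normal at zero with configurable mean and spread; the default
    mean of 275 bp reflects sequencing the start of a 200-300 bp 3'-end
    fragment.
    """

    mean_offset: float = 275.0
    spread: float = 25.0

    def __post_init__(self) -> None:
        if self.mean_offset < 0 or self.spread < 0:
            raise ValueError("mean_offset and spread must be >= 0")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.spread == 0:
            return np.full(n, self.mean_offset)
        d = rng.normal(self.mean_offset, self.spread, size=n)
        # truncate at 0 by resampling the (rare) negative draws
        bad = d < 0
        while bad.any():
            d[bad] = rng.normal(self.mean_offset, self.spread, size=int(bad.sum()))
            bad = d < 0
        return d


@dataclass(frozen=True)
class NovelLocus:
    """A transcribed region hidden from the annotation (ground-truth novel)."""

    locus_id: str
    chrom: str
    start: int
    end: int
    strand: str

    @property
    def three_prime(self) -> int:
        """Half-open boundary coordinate of the 3' end."""
        return self.end if self.strand == "+" else self.start


@dataclass
class CohortDesign:
    """Design of a multi-class cohort.

    expressed_peak_truth maps locus id -> (set of expressing class labels,
    mean expression level). Levels are relative weights: within a sample the
    non-background read mass is split across that sample's expressed loci in
    proportion to their levels.
    """

    classes: Sequence[str]
    samples_per_class: int
    expressed_peak_truth: Mapping[str, tuple[set, float]]
    library_size: int = 5000
    background_rate: float = 0.05
    multimap_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ValueError("library_size must be > 0")
        for name, frac in (
            ("background_rate", self.background_rate),
            ("multimap_fraction", self.multimap_fraction),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for locus, (cls, level) in self.expressed_peak_truth.items():
            if level < 0:
                raise ValueError(f"locus {locus}: expression level must be >= 0")
            unknown = set(cls) - set(self.classes)
            if unknown:
                raise ValueError(f"locus {locus}: unknown classes {unknown}")

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"{cls}_{i + 1}" for cls in self.classes for i in range(self.samples_per_class)
        ]

    @property
    def sample_class(self) -> dict[str, str]:
        return {sid: sid.rsplit("_", 1)[0] for sid in self.sample_ids}


def read_start_position(candidate: Candidate, read_length: int = READ_LENGTH) -> int:
    """5'-most sequenced position of an alignment in read orientation.

    Leftmost base for + strand, rightmost base for - strand.
    """
    if candidate.strand == "+":
        return candidate.start
    return candidate.start + read_length - 1


def _feature_span(kind: str, rng: np.random.Generator) -> int:
    if kind == "coding":
        return int(rng.integers(2000, 8001))
    if kind == "lncrna":
        return int(rng.integers(1000, 4001))
    return int(rng.integers(500, 2001))  # hidden novel locus


def _make_exons(start: int, end: int, n_exons: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Split [start, end) into n_exons exons separated by introns."""
    if n_exons == 1:
        return [(start, end)]
    span = end - start
    # pick 2*(n_exons-1) interior cut points; alternate exon/intron blocks
    cuts = np.sort(rng.choice(np.arange(1, span), size=2 * (n_exons - 1), replace=False))
    bounds = [start] + (start + cuts).tolist() + [end]
    return [(bounds[2 * i], bounds[2 * i + 1]) for i in range(n_exons)]


def make_toy_annotation(
    genome: ToyGenome,
    n_coding: int,
    n_lncrna: int,
    n_unannotated_loci: int,
    seed: int = 0,
    min_gap: int = 11_000,
) -> tuple[list[TranscriptModel], list[NovelLocus]]:
    """Place non-overlapping transcripts and hidden novel loci on the genome.

    Features are laid out left to right across chromosomes with random gaps of
    at least ``min_gap`` bp between feature boundaries, which guarantees the
    hidden loci are more than 5 kb from every annotated transcript (and
    outside 5 kb flanks). Raises ValueError when the genome is too small.
    """
    if min(n_coding, n_lncrna, n_unannotated_loci) < 0:
        raise ValueError("feature counts must be >= 0")
    rng = np.random.default_rng(seed)
    kinds = ["coding"] * n_coding + ["lncrna"] * n_lncrna + ["novel"] * n_unannotated_loci
    rng.shuffle(kinds)

    transcripts: list[TranscriptModel] = []
    novel: list[NovelLocus] = []
    chroms = list(genome.chrom_sizes)
    ci = 0
    cursor = int(rng.integers(min_gap, 2 * min_gap))
    counters = {"coding": 0, "lncrna": 0, "novel": 0}
    for kind in kinds:
        span = _feature_span(kind, rng)
        while ci < len(chroms) and cursor + span + min_gap > genome.chrom_sizes[chroms[ci]]:
            ci += 1
            cursor = int(rng.integers(min_gap, 2 * min_gap))
        if ci >= len(chroms):
            raise ValueError(
                "genome too small to place the requested features with the "
                f"required {min_gap} bp spacing"
            )
        chrom = chroms[ci]
        start, end = cursor, cursor + span
        strand = "+" if rng.random() < 0.5 else "-"
        counters[kind] += 1
        if kind == "novel":
            novel.append(NovelLocus(f"novel_{counters[kind]}", chrom, start, end, strand))
        else:
            n_exons = int(rng.integers(2, 5)) if kind == "coding" else int(rng.integers(1, 3))
            n_exons = min(n_exons, max(1, span // 300))
            transcripts.append(
                TranscriptModel(
                    transcript_id=f"{kind}_{counters[kind]}",
                    chrom=chrom,
                    strand=strand,
                    exons=_make_exons(start, end, n_exons, rng),
                    is_coding=(kind == "coding"),
                    source="refseq-like" if kind == "coding" else "lncRNA-catalog-1",
                )
            )
        cursor = end + int(rng.integers(min_gap, 2 * min_gap))
    return transcripts, novel


def _three_prime(feature) -> tuple[str, int, str]:
    """(chrom, half-open 3' boundary coordinate, strand) of a feature."""
    if isinstance(feature, NovelLocus):
        return feature.chrom, feature.three_prime, feature.strand
    return feature.chrom, feature.three_prime, feature.strand


def simulate_3seq_sample(
    loci: Sequence,
    truth: Mapping[str, float],
    offsets: FragmentOffsetModel,
    library_size: int,
    background_rate: float,
    multimap_fraction: float,
    seed: int,
    genome: ToyGenome,
    sample_id: str = "S",
) -> list[AlignmentRecord]:
    """Simulate one 3'-tag library as a list of alignment records.

    loci is any sequence of objects with ``.chrom``, ``.strand``, and a
    ``three_prime`` half-open boundary (TranscriptModel or NovelLocus), keyed
    by id in ``truth``. Exactly ``library_size`` records are returned.
    Signal reads sit on the locus strand with 5' starts ~offsets upstream of
    the 3' end; background reads are uniform over the genome on random
    strands; a ``multimap_fraction`` of reads carries 1-3 decoy candidate
    alignments with mismatch counts in {0, 1, 2}.
    """
    if any(v < 0 for v in truth.values()):
        raise ValueError("truth expression levels must be >= 0")
    rng = np.random.default_rng(seed)
    by_id = {getattr(l, "transcript_id", getattr(l, "locus_id", None)): l for l in loci}
    expressed = [(lid, lvl) for lid, lvl in truth.items() if lvl > 0]
    for lid, _ in expressed:
        if lid not in by_id:
            raise ValueError(f"truth locus {lid!r} not among the provided loci")

    weights = np.array([lvl for _, lvl in expressed], dtype=float)
    if weights.size and weights.sum() > 0:
        p_signal = (1.0 - background_rate) * weights / weights.sum()
        probs = np.concatenate([p_signal, [background_rate]])
    else:
        probs = np.array([1.0])  # background only
    counts = rng.multinomial(library_size, probs)

    chroms = list(genome.chrom_sizes)
    sizes = np.array([genome.chrom_sizes[c] for c in chroms], dtype=float)
    records: list[AlignmentRecord] = []

    def _emit(chrom: str, start5: int, strand: str) -> None:
        """Append one record whose 5' read start is start5 on strand."""
        left = start5 if strand == "+" else start5 - (READ_LENGTH - 1)
        size = genome.chrom_sizes[chrom]
        left = int(np.clip(left, 0, size - READ_LENGTH))
        m_true = min(2, int(rng.binomial(READ_LENGTH, 0.01)))
        cands = [Candidate(chrom, left, strand, m_true)]
        if rng.random() < multimap_fraction:
            for _ in range(int(rng.integers(1, 4))):
                dc = chroms[int(rng.integers(len(chroms)))]
                dpos = int(rng.integers(0, genome.chrom_sizes[dc] - READ_LENGTH + 1))
                dstrand = "+" if rng.random() < 0.5 else "-"
                dm = int(rng.integers(0, 3))
                cands.append(Candidate(dc, dpos, dstrand, dm))
        records.append(
            AlignmentRecord(f"{sample_id}_r{len(records) + 1}", READ_LENGTH, cands)
        )

    for (lid, _), n in zip(expressed, counts[: len(expressed)]):
        if n == 0:
            continue
        locus = by_id[lid]
        chrom, tp, strand = _three_prime(locus)
        d = np.rint(offsets.sample(rng, int(n))).astype(int)
        if strand == "+":
            starts5 = tp - d  # upstream = lower coordinate
        else:
            starts5 = tp + d  # upstream = higher coordinate
        for s5 in starts5:
            _emit(chrom, int(s5), strand)

    n_bg = int(counts[-1]) if expressed else int(counts[0])
    if n_bg:
        ci = rng.choice(len(chroms), size=n_bg, p=sizes / sizes.sum())
        for i in range(n_bg):
            chrom = chroms[int(ci[i])]
            pos = int(rng.integers(0, genome.chrom_sizes[chrom]))
            strand = "+" if rng.random() < 0.5 else "-"
            _emit(chrom, pos, strand)

    rng.shuffle(records)  # interleave signal and background
    # re-number after the shuffle so ids are stable and deterministic
    for i, rec in enumerate(records):
        rec.read_id = f"{sample_id}_r{i + 1}"
    return records


def simulate_cohort(
    design: CohortDesign,
    annotation: Sequence[TranscriptModel],
    novel_loci: Sequence[NovelLocus],
    genome: ToyGenome,
    offsets: FragmentOffsetModel | None = None,
) -> tuple[dict[str, list[AlignmentRecord]], "pd.DataFrame"]:
    """Simulate every sample of a cohort; returns (reads by sample, truth table).

    One master seed drives the whole cohort: each sample gets a child seed
    drawn deterministically from the design seed, so identical designs give
    bit-identical cohorts. The truth table records, per locus, the expressing
    classes and level — the reference for parameter-recovery tests.
    """
    import pandas as pd

    offsets = offsets or FragmentOffsetModel()
    loci = list(annotation) + list(novel_loci)
    _check_loci_in_genome(loci, genome)
    seed_rng = np.random.default_rng(design.seed)
    sample_seeds = seed_rng.integers(0, 2**31 - 1, size=len(design.sample_ids))
    reads: dict[str, list[AlignmentRecord]] = {}
    for sid, sseed in zip(design.sample_ids, sample_seeds):
        cls = design.sample_class[sid]
        truth = {
            lid: lvl
            for lid, (classes, lvl) in design.expressed_peak_truth.items()
            if cls in classes
        }
        reads[sid] = simulate_3seq_sample(
            loci,
            truth,
            offsets,
            design.library_size,
            design.background_rate,
            design.multimap_fraction,
            seed=int(sseed),
            genome=genome,
            sample_id=sid,
        )
    by_id = {getattr(l, "transcript_id", getattr(l, "locus_id", None)): l for l in loci}
    rows = []
    for lid, (classes, lvl) in design.expressed_peak_truth.items():
        locus = by_id[lid]
        chrom, tp, strand = _three_prime(locus)
        rows.append(
            {
                "locus_id": lid,
                "chrom": chrom,
                "three_prime": tp,
                "strand": strand,
                "classes": ",".join(sorted(classes)),
                "level": lvl,
                "class_specific": len(classes) < len(design.classes),
            }
        )
    return reads, pd.DataFrame(rows)


def _check_loci_in_genome(loci: Sequence, genome: ToyGenome) -> None:
    for locus in loci:
        chrom = locus.chrom
        end = locus.exons[-1][1] if hasattr(locus, "exons") else locus.end
        if chrom not in genome.chrom_sizes or end > genome.chrom_sizes[chrom]:
            raise ValueError(f"locus outside the genome: {locus}")


# ---------------------------------------------------------------------------
# plain-text writers


def write_alignments_bed(records: Sequence[AlignmentRecord], bed_path, sidecar_path) -> None:
    """Write records as 6-column BED (best candidate per line per candidate)
    plus a sidecar TSV of the full candidate mismatch sets.

    BED score column carries the mismatch count of that alignment.
    """
    with open(bed_path, "w") as bed, open(sidecar_path, "w") as side:
        side.write("read_id\tcandidates\n")
        for rec in records:
            for c in rec.candidates:
                bed.write(
                    f"{c.chrom}\t{c.start}\t{c.start + rec.read_length}\t"
                    f"{rec.read_id}\t{c.mismatches}\t{c.strand}\n"
                )
            side.write(
                rec.read_id
                + "\t"
                + ";".join(
                    f"{c.chrom}:{c.start}:{c.strand}:{c.mismatches}" for c in rec.candidates
                )
                + "\n"
            )


def read_alignments_bed(bed_path, sidecar_path=None, read_length: int = READ_LENGTH) -> list[AlignmentRecord]:
    """Read the BED + sidecar format back into alignment records."""
    if sidecar_path is not None:
        records = []
        with open(sidecar_path) as side:
            header = side.readline()
            for line in side:
                read_id, blob = line.rstrip("\n").split("\t")
                cands = []
                for tok in blob.split(";"):
                    chrom, start, strand, m = tok.rsplit(":", 3)
                    cands.append(Candidate(chrom, int(start), strand, int(m)))
                records.append(AlignmentRecord(read_id, read_length, cands))
        return records
    by_read: dict[str, list[Candidate]] = {}
    order: list[str] = []
    with open(bed_path) as bed:
        for line in bed:
            chrom, start, end, name, score, strand = line.rstrip("\n").split("\t")[:6]
            if name not in by_read:
                by_read[name] = []
                order.append(name)
            by_read[name].append(Candidate(chrom, int(start), strand, int(score)))
    return [AlignmentRecord(name, read_length, by_read[name]) for name in order]


def write_annotation_bed12(transcripts: Sequence[TranscriptModel], path) -> None:
    """Write transcript models as BED12 (one line per transcript)."""
    with open(path, "w") as fh:
        for t in transcripts:
            start = t.exons[0][0]
            end = t.exons[-1][1]
            sizes = ",".join(str(e - s) for s, e in t.exons) + ","
            offsets = ",".join(str(s - start) for s, _ in t.exons) + ","
            fh.write(
                f"{t.chrom}\t{start}\t{end}\t{t.transcript_id}\t0\t{t.strand}\t"
                f"{start}\t{end if t.is_coding else start}\t0\t{len(t.exons)}\t"
                f"{sizes}\t{offsets}\n"
            )


def write_truth_tsv(truth_df, path) -> None:
    truth_df.to_csv(path, sep="\t", index=False)
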