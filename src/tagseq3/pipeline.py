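"""End-to-end orchestration: simulate/load -> filter -> peaks -> annotate ->
quantify -> differential expression, with deterministic artifacts.

The pipeline is a pure function of (inputs, config, seed): every stage's
output file is hashed into the run report, and re-running an identical
configuration reproduces identical hashes. Stage order follows the analysis
chain of a 3'-tag experiment: ambiguity filtering of alignments, pooled
strand-specific peak calling, annotation-hierarchy classification, count
matrix and normalisation, then one-vs-rest SAM.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import align_filter, annotation, expression, io, peaks, sam, synthetic

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs", "build_default_truth"]


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run."""

    output_dir: Path
    seed: int = 0
    simulate: dict | None = None
    reads_manifest: Path | None = None  # TSV: sample_id, class, bed, sidecar
    annotation_bed12: Path | None = None
    aux_tracks: dict[str, Path] = field(default_factory=dict)
    filter_params: align_filter.FilterParams = field(default_factory=align_filter.FilterParams)
    peak_params: peaks.PeakCallParams = field(default_factory=peaks.PeakCallParams)
    annotation_params: annotation.AnnotationParams = field(default_factory=annotation.AnnotationParams)
    sd_min: float = 0.25
    target_fdr: float = 0.05
    n_permutations: int = 200

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any], base: Path = Path(".")) -> "PipelineConfig":
        def _path(key):
            return (base / raw[key]) if key in raw and raw[key] else None

        return cls(
            output_dir=base / raw.get("output_dir", "out"),
            seed=int(raw.get("seed", 0)),
            simulate=raw.get("simulate"),
            reads_manifest=_path("reads_manifest"),
            annotation_bed12=_path("annotation_bed12"),
            aux_tracks={k: base / v for k, v in raw.get("aux_tracks", {}).items()},
            filter_params=align_filter.FilterParams(**raw.get("filter", {})),
            peak_params=peaks.PeakCallParams(**raw.get("peaks", {})),
            annotation_params=annotation.AnnotationParams(**raw.get("annotate", {})),
            sd_min=float(raw.get("expression", {}).get("sd_min", 0.25)),
            target_fdr=float(raw.get("diffexp", {}).get("fdr", 0.05)),
            n_permutations=int(raw.get("diffexp", {}).get("permutations", 200)),
        )


def build_default_truth(
    transcripts,
    novel_loci,
    classes,
    specific_per_class: int = 1,
    n_shared: int = 3,
    level_specific: float = 10.0,
    level_shared: float = 5.0,
) -> dict[str, tuple[set, float]]:
    """Ground truth with one (or more) class-specific locus per class, taken
    from the novel/lncRNA loci, plus shared loci expressed everywhere."""
    specific_pool = list(novel_loci) + [t for t in transcripts if not t.is_coding]
    shared_pool = [t for t in transcripts if t.is_coding] or list(transcripts)
    need = specific_per_class * len(classes)
    if len(specific_pool) < need:
        raise ValueError(f"need {need} class-specific loci, have {len(specific_pool)}")
    truth: dict[str, tuple[set, float]] = {}
    i = 0
    for cls in classes:
        for _ in range(specific_per_class):
            locus = specific_pool[i]
            lid = getattr(locus, "transcript_id", getattr(locus, "locus_id", None))
            truth[lid] = ({cls}, level_specific)
            i += 1
    for t in shared_pool[:n_shared]:
        truth[t.transcript_id] = (set(classes), level_shared)
    return truth


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_inputs(config: PipelineConfig) -> list[str]:
    """Report malformed inputs (never mutates them); empty list when clean."""
    problems: list[str] = []
    if config.annotation_bed12 is not None:
        if not Path(config.annotation_bed12).exists():
            problems.append(f"annotation file missing: {config.annotation_bed12}")
        else:
            try:
                io.read_bed12(config.annotation_bed12)
            except (ValueError, IndexError) as exc:
                problems.append(f"malformed annotation: {exc}")
    if config.reads_manifest is not None:
        if not Path(config.reads_manifest).exists():
            problems.append(f"manifest missing: {config.reads_manifest}")
        else:
            manifest = pd.read_csv(config.reads_manifest, sep="\t")
            for col in ("sample_id", "class", "bed"):
                if col not in manifest.columns:
                    problems.append(f"manifest lacks column {col!r}")
            if "bed" in manifest.columns:
                base = Path(config.reads_manifest).parent
                for _, row in manifest.iterrows():
                    bed = base / row["bed"]
                    if not bed.exists():
                        problems.append(f"sample {row['sample_id']}: reads file missing: {bed}")
                        continue
                    with open(bed) as fh:
                        for ln, line in enumerate(fh, 1):
                            f = line.rstrip("\n").split("\t")
                            if len(f) < 6:
                                problems.append(f"{bed}:{ln}: fewer than 6 BED columns")
                                break
                            if int(f[1]) >= int(f[2]):
                                problems.append(f"{bed}:{ln}: start >= end")
                            if f[5] not in "+-":
                                problems.append(f"{bed}:{ln}: bad strand {f[5]!r}")
    return problems


def _simulate_stage(config: PipelineConfig, outdir: Path, log: list[dict]):
    sim = config.simulate
    genome = synthetic.ToyGenome(
        dict(sim["chrom_sizes"]), sim.get("mappable_size")
    )
    transcripts, novel = synthetic.make_toy_annotation(
        genome,
        n_coding=int(sim.get("n_coding", 20)),
        n_lncrna=int(sim.get("n_lncrna", 5)),
        n_unannotated_loci=int(sim.get("n_unannotated", 5)),
        seed=config.seed,
    )
    classes = list(sim["classes"])
    truth = sim.get("truth") or build_default_truth(
        transcripts,
        novel,
        classes,
        specific_per_class=int(sim.get("specific_per_class", 1)),
        n_shared=int(sim.get("n_shared", 3)),
    )
    truth = {k: (set(v[0]) if not isinstance(v[0], set) else v[0], v[1]) for k, v in truth.items()}
    design = synthetic.CohortDesign(
        classes=classes,
        samples_per_class=int(sim.get("samples_per_class", 3)),
        expressed_peak_truth=truth,
        library_size=int(sim.get("library_size", 5000)),
        background_rate=float(sim.get("background_rate", 0.05)),
        multimap_fraction=float(sim.get("multimap_fraction", 0.1)),
        seed=config.seed,
    )
    reads, truth_df = synthetic.simulate_cohort(design, transcripts, novel, genome)
    synthetic.write_annotation_bed12(transcripts, outdir / "annotation.bed12")
    synthetic.write_truth_tsv(truth_df, outdir / "truth.tsv")
    log.append(
        {
            "stage": "simulate",
            "n_samples": len(reads),
            "n_transcripts": len(transcripts),
            "n_novel_loci": len(novel),
        }
    )
    return reads, design.sample_class, transcripts, truth_df


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order; returns the report (also written as JSON)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []

    problems = validate_inputs(config)
    if problems:
        raise ValueError("input validation failed: " + "; ".join(problems))

    truth_df = None
    if config.simulate is not None:
        records_by_sample, sample_class, transcripts, truth_df = _simulate_stage(
            config, outdir, log
        )
    elif config.reads_manifest is not None:
        manifest = pd.read_csv(config.reads_manifest, sep="\t")
        base = Path(config.reads_manifest).parent
        records_by_sample = {}
        sample_class = {}
        for _, row in manifest.iterrows():
            sidecar = base / row["sidecar"] if "sidecar" in row and pd.notna(row["sidecar"]) else None
            records_by_sample[row["sample_id"]] = synthetic.read_alignments_bed(
                base / row["bed"], sidecar
            )
            sample_class[row["sample_id"]] = row["class"]
        transcripts = io.read_bed12(config.annotation_bed12) if config.annotation_bed12 else []
    else:
        raise ValueError("config needs either a simulate block or a reads manifest")

    # stage: posterior filter
    starts_by_sample: dict[str, list[peaks.ReadStart]] = {}
    n_in = n_kept = 0
    for sample, records in sorted(records_by_sample.items()):
        res = align_filter.filter_reads(records, config.filter_params)
        n_in += len(records)
        n_kept += res.n_kept
        bed = outdir / f"filtered_{sample}.bed"
        io.write_kept_reads_bed(res.kept, synthetic.READ_LENGTH, bed)
        starts_by_sample[sample] = [
            peaks.ReadStart(
                c.chrom, c.strand, synthetic.read_start_position(c), sample
            )
            for _, c in res.kept
        ]
    log.append({"stage": "filter", "reads_in": n_in, "reads_kept": n_kept})

    # stage: peak calling
    pooled = [r for starts in starts_by_sample.values() for r in starts]
    stages = peaks.call_and_filter(pooled, transcripts, config.peak_params)
    final_peaks = stages["final"]
    io.write_peaks_bed(final_peaks, outdir / "peaks.bed")
    log.append(
        {
            "stage": "call_peaks",
            "initial": len(stages["initial"]),
            "antisense_removed": len(stages["antisense_removed"]),
            "final": len(final_peaks),
        }
    )

    # stage: annotation
    aux = {name: io.read_aux_bed(path) for name, path in config.aux_tracks.items()}
    annotations = annotation.annotate_peaks(
        final_peaks, transcripts, config.annotation_params, aux
    )
    ann_df = pd.DataFrame(
        {
            "peak_id": [a.peak_id for a in annotations],
            "category": [a.category for a in annotations],
            "in_3prime_exon": [a.in_3prime_exon for a in annotations],
            "distance_to_3prime": [a.distance_to_3prime for a in annotations],
            "aux_flags": [",".join(sorted(a.aux_flags)) for a in annotations],
        }
    )
    ann_df.to_csv(outdir / "peak_annotation.tsv", sep="\t", index=False)
    counts = annotation.category_counts(annotations)
    pd.Series(counts, name="n_peaks").rename_axis("category").to_csv(
        outdir / "category_counts.tsv", sep="\t"
    )
    log.append({"stage": "annotate", **counts})

    # stage: expression
    raw = expression.count_reads_in_peaks(starts_by_sample, final_peaks, sample_class)
    raw.to_tsv(outdir / "matrix_raw.tsv")
    norm = expression.normalize(raw)
    norm.to_tsv(outdir / "matrix_normalized.tsv")
    variable = expression.variability_filter(norm, config.sd_min)
    log.append(
        {
            "stage": "quantify",
            "n_peaks": len(raw.peak_ids),
            "in_peak_reads": int(raw.values.to_numpy().sum()),
            "n_variable": len(variable),
        }
    )

    # stage: one-vs-rest SAM
    summary = sam.one_vs_rest(
        norm,
        n_permutations=config.n_permutations,
        seed=config.seed,
        target_fdr=config.target_fdr,
    )
    summary.summary().to_csv(outdir / "sam_summary.tsv", sep="\t")
    for cls, res in summary.results.items():
        res.summary().to_csv(outdir / f"sam_{cls}.tsv", sep="\t")
    log.append(
        {
            "stage": "diffexp",
            "n_contrasts": len(summary.results),
            "union_called": len(summary.union),
            "overall_fdr": summary.overall_fdr,
            "skipped": summary.skipped,
        }
    )

    artifacts = sorted(p.name for p in outdir.iterdir() if p.suffix in (".bed", ".tsv", ".bed12"))
    report = {
        "seed": config.seed,
        "stages": log,
        "called_by_class": {c: sorted(r.called) for c, r in summary.results.items()},
        "artifact_hashes": {name: _sha256(outdir / name) for name in artifacts},
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
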