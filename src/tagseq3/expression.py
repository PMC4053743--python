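"""Peak expression matrices: counting, normalisation, filtering, clustering.

The unit of quantification is the peak: for each sample the reads whose
start position falls inside a peak's interval on the peak's strand are
tallied. Raw counts are depth-normalised per sample by dividing by that
sample's mean count over all peaks, then variance-compressed by a square
root:

    y_ij = sqrt( x_ij / mean_j(x) )

so each normalised sample satisfies mean(y^2) = 1. Variable peaks are those
with a standard deviation above a cutoff (default 0.25) over a chosen sample
subset; rows are median-centred before average-linkage hierarchical
clustering under a centred-correlation (1 - Pearson) distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist
from scipy.stats import mannwhitneyu, pearsonr

from .peaks import Peak, ReadStart

__all__ = [
    "ExpressionMatrix",
    "SummaryStats",
    "count_reads_in_peaks",
    "normalize",
    "variability_filter",
    "median_center",
    "hierarchical_cluster",
    "summarize_categories",
    "replicate_correlation",
]


@dataclass
class ExpressionMatrix:
    """Peaks x samples values with class labels and a processing stage tag."""

    values: pd.DataFrame  # rows = peaks, columns = samples
    sample_class: dict[str, str]
    stage: str = "raw"  # raw | normalized | median_centered

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.sample_class)
        if missing:
            raise ValueError(f"samples without a class label: {sorted(missing)}")
        if self.stage == "raw" and (self.values.to_numpy() < 0).any():
            raise ValueError("negative raw counts")

    @property
    def peak_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="peak_id")

    @classmethod
    def from_tsv(cls, path, sample_class: Mapping[str, str], stage: str = "raw"):
        values = pd.read_csv(path, sep="\t", index_col="peak_id")
        return cls(values, dict(sample_class), stage)


def count_reads_in_peaks(
    reads_by_sample: Mapping[str, Iterable],
    peaks: Sequence[Peak],
    sample_class: Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Raw count matrix: read start in [peak.start, peak.end) on the peak's
    strand. Peaks are disjoint per strand, so each read counts at most once.

    Reads may be ReadStart objects or (chrom, strand, pos) triples.
    """
    # sorted peak-start arrays per (chrom, strand) for binary search
    by_key: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, list[str]]] = {}
    for key in {(p.chrom, p.strand) for p in peaks}:
        ps = sorted((p for p in peaks if (p.chrom, p.strand) == key), key=lambda p: p.start)
        by_key[key] = (
            np.array([p.start for p in ps]),
            np.array([p.end for p in ps]),
            [p.peak_id for p in ps],
        )
    samples = list(reads_by_sample)
    values = pd.DataFrame(
        0, index=[p.peak_id for p in peaks], columns=samples, dtype=float
    )
    for sample, reads in reads_by_sample.items():
        for r in reads:
            chrom, strand, pos = (
                (r.chrom, r.strand, r.pos) if isinstance(r, ReadStart) else (r[0], r[1], r[2])
            )
            entry = by_key.get((chrom, strand))
            if entry is None:
                continue
            starts, ends, ids = entry
            i = int(np.searchsorted(starts, pos, side="right")) - 1
            if i >= 0 and pos < ends[i]:
                values.at[ids[i], sample] += 1
    classes = dict(sample_class) if sample_class else {s: "unknown" for s in samples}
    return ExpressionMatrix(values, classes, stage="raw")


def normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Depth-normalise and compress: y = sqrt(x / sample mean).

    Only valid on a raw matrix (stage tracking rejects re-normalisation);
    an all-zero sample is an error naming the sample.
    """
    if matrix.stage != "raw":
        raise ValueError(f"normalize expects a raw matrix, got stage {matrix.stage!r}")
    means = matrix.values.mean(axis=0)
    zero = means[means == 0]
    if len(zero):
        raise ValueError(f"sample(s) with all-zero counts: {list(zero.index)}")
    y = np.sqrt(matrix.values / means)
    return replace(matrix, values=y, stage="normalized")


def variability_filter(
    matrix: ExpressionMatrix,
    sd_min: float = 0.25,
    sample_subset: Sequence[str] | None = None,
) -> list[str]:
    """Peak ids whose standard deviation (n-1 denominator) over the subset
    exceeds ``sd_min``. The subset defaults to all samples; pass the cancer
    samples to reproduce the cancer-only selection."""
    cols = list(sample_subset) if sample_subset is not None else matrix.sample_ids
    sd = matrix.values[cols].std(axis=1, ddof=1)
    return list(sd.index[sd > sd_min])


def median_center(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each peak row's median; every output row has median 0."""
    centered = matrix.values.sub(matrix.values.median(axis=1), axis=0)
    return replace(matrix, values=centered, stage="median_centered")


def _correlation_distance(data: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distance; constant rows treated as correlation 0."""
    centered = data - data.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    safe = np.where(norms == 0, 1.0, norms)
    unit = centered / safe[:, None]
    corr = unit @ unit.T
    corr[norms == 0, :] = 0.0
    corr[:, norms == 0] = 0.0
    np.fill_diagonal(corr, 1.0)
    d = 1.0 - corr
    iu = np.triu_indices_from(d, k=1)
    return np.maximum(d[iu], 0.0)


def hierarchical_cluster(
    matrix: ExpressionMatrix, cluster_columns: bool = True
) -> dict[str, list[str]]:
    """Average-linkage clustering of peaks (rows) and samples (columns)
    under centred-correlation distance; returns the dendrogram leaf orders."""
    data = matrix.values.to_numpy(dtype=float)
    out: dict[str, list[str]] = {}
    row_order = leaves_list(average(_correlation_distance(data)))
    out["rows"] = [matrix.peak_ids[i] for i in row_order]
    if cluster_columns:
        col_order = leaves_list(average(_correlation_distance(data.T)))
        out["columns"] = [matrix.sample_ids[i] for i in col_order]
    return out


@dataclass
class SummaryStats:
    """Category-level and cancer-vs-normal summary statistics."""

    category_means: dict[str, float]
    category_tests: dict[tuple[str, str], float]  # rank-test p per category pair
    n_above_threshold_normal: int | None = None
    frac_cancer_max_higher: float | None = None
    mean_expression_correlation: float | None = None
    empty_categories: list[str] = field(default_factory=list)


def summarize_categories(
    matrix: ExpressionMatrix,
    peak_category: Mapping[str, str],
    normal_matrix: ExpressionMatrix | None = None,
    threshold: float = 0.4,
) -> SummaryStats:
    """Per-category mean expression with rank-based pairwise tests, plus
    cancer-vs-normal comparisons when a normal-cohort matrix is supplied:
    the count of peaks exceeding ``threshold`` in at least one normal sample,
    the fraction whose maximal cancer sample exceeds the maximal normal
    sample, and the Pearson correlation of per-peak means."""
    peak_means = matrix.values.mean(axis=1)
    by_cat: dict[str, list[float]] = {cat: [] for cat in set(peak_category.values())}
    for pid, cat in peak_category.items():
        if pid in peak_means.index:
            by_cat[cat].append(float(peak_means[pid]))
    empty = [c for c, v in by_cat.items() if not v]
    cat_means = {c: float(np.mean(v)) for c, v in by_cat.items() if v}
    tests: dict[tuple[str, str], float] = {}
    cats = sorted(cat_means)
    for i, a in enumerate(cats):
        for b in cats[i + 1 :]:
            if len(by_cat[a]) >= 2 and len(by_cat[b]) >= 2:
                tests[(a, b)] = float(mannwhitneyu(by_cat[a], by_cat[b]).pvalue)
    stats = SummaryStats(cat_means, tests, empty_categories=empty)
    if normal_matrix is not None:
        shared = matrix.values.index.intersection(normal_matrix.values.index)
        cancer = matrix.values.loc[shared]
        normal = normal_matrix.values.loc[shared]
        stats.n_above_threshold_normal = int((normal.max(axis=1) > threshold).sum())
        stats.frac_cancer_max_higher = float(
            (cancer.max(axis=1) > normal.max(axis=1)).mean()
        )
        cm, nm = cancer.mean(axis=1), normal.mean(axis=1)
        if len(shared) >= 2 and cm.std() > 0 and nm.std() > 0:
            stats.mean_expression_correlation = float(pearsonr(cm, nm)[0])
        elif len(shared) >= 2 and cm.equals(nm):
            stats.mean_expression_correlation = 1.0
    return stats


def replicate_correlation(matrix: ExpressionMatrix, pairs: Sequence[tuple[str, str]]) -> dict[tuple[str, str], float]:
    """Squared Pearson correlation (r^2) between technical-replicate columns."""
    out = {}
    for a, b in pairs:
        x, y = matrix.values[a], matrix.values[b]
        if x.equals(y):
            out[(a, b)] = 1.0
        else:
            out[(a, b)] = float(pearsonr(x, y)[0] ** 2)
    return out
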