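"""Posterior filtering of ambiguously mapped 3'-tag reads.

Short single-end tags frequently align to several genomic locations. Each
candidate alignment of a read of length ``L`` with ``m`` mismatches is scored
under a binomial sequencing-error model with a constant per-base substitution
rate ``eps``:

    likelihood = eps**m * (1 - eps)**(L - m)

(the binomial coefficient is identical across candidate alignments of the
same read and cancels in every ratio, so it is omitted). The posterior
probability of the best (minimum-mismatch) alignment is its likelihood divided
by the sum of likelihoods over all candidates. A read is retained, with its
best alignment only, when that posterior reaches a threshold (default 0.8);
two candidates tied at the minimum mismatch count give a posterior of at most
0.5 and are therefore always rejected at the default threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Candidate",
    "AlignmentRecord",
    "FilterParams",
    "alignment_likelihood",
    "posterior_best",
    "filter_reads",
]


@dataclass(frozen=True, order=True)
class Candidate:
    """One candidate genomic alignment of a read."""

    chrom: str
    start: int  # 0-based leftmost aligned base
    strand: str
    mismatches: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.mismatches < 0:
            raise ValueError("mismatch count must be >= 0")


@dataclass
class AlignmentRecord:
    """A sequenced tag with all of its candidate alignments."""

    read_id: str
    read_length: int
    candidates: list[Candidate]

    def __post_init__(self) -> None:
        if not self.candidates:
            raise ValueError(f"read {self.read_id}: at least one candidate required")
        for c in self.candidates:
            if c.mismatches > self.read_length:
                raise ValueError(
                    f"read {self.read_id}: {c.mismatches} mismatches exceeds "
                    f"read length {self.read_length}"
                )


@dataclass(frozen=True)
class FilterParams:
    """Parameters of the ambiguity filter.

    error_rate
        Per-base substitution probability of the sequencer (default 0.01).
    posterior_min
        Minimum posterior probability of the best alignment for a read to be
        kept (default 0.8).
    """

    error_rate: float = 0.01
    posterior_min: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 < self.error_rate < 1.0:
            raise ValueError("error_rate must be in (0, 1)")
        if not 0.0 < self.posterior_min <= 1.0:
            raise ValueError("posterior_min must be in (0, 1]")


def alignment_likelihood(mismatches: int, read_length: int, error_rate: float) -> float:
    """Likelihood of one alignment under the binomial error model.

    Returns ``error_rate**m * (1 - error_rate)**(L - m)``; strictly decreasing
    in ``m`` whenever ``error_rate < 0.5``.
    """
    if mismatches < 0 or mismatches > read_length:
        raise ValueError(
            f"mismatch count {mismatches} outside [0, {read_length}]"
        )
    return error_rate**mismatches * (1.0 - error_rate) ** (read_length - mismatches)


def _log_likelihoods(record: AlignmentRecord, error_rate: float) -> np.ndarray:
    m = np.array([c.mismatches for c in record.candidates], dtype=float)
    return m * math.log(error_rate) + (record.read_length - m) * math.log1p(-error_rate)


def candidate_posteriors(record: AlignmentRecord, params: FilterParams) -> np.ndarray:
    """Posterior probability of each candidate alignment (sums to 1).

    Computed in log space, normalised by the maximum before exponentiation so
    long reads cannot underflow.
    """
    ll = _log_likelihoods(record, params.error_rate)
    w = np.exp(ll - ll.max())
    return w / w.sum()


def posterior_best(record: AlignmentRecord, params: FilterParams | None = None) -> float:
    """Posterior probability of the best (minimum-mismatch) alignment."""
    params = params or FilterParams()
    return float(candidate_posteriors(record, params).max())


def best_candidate(record: AlignmentRecord) -> Candidate:
    """Minimum-mismatch candidate; ties broken by (chrom, start, strand)."""
    return min(record.candidates, key=lambda c: (c.mismatches, c.chrom, c.start, c.strand))


@dataclass
class FilterResult:
    """Outcome of :func:`filter_reads`."""

    kept: list[tuple[str, Candidate]] = field(default_factory=list)
    rejected: list[tuple[str, float]] = field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return len(self.kept)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def filter_reads(
    records: Iterable[AlignmentRecord], params: FilterParams | None = None
) -> FilterResult:
    """Keep reads whose best-alignment posterior reaches the threshold.

    Each kept read contributes its single best alignment; the rejection log
    records (read_id, posterior) for the rest. Kept plus rejected counts
    always sum to the input count.
    """
    params = params or FilterParams()
    out = FilterResult()
    for rec in records:
        p = posterior_best(rec, params)
        if p >= params.posterior_min:
            out.kept.append((rec.read_id, best_candidate(rec)))
        else:
            out.rejected.append((rec.read_id, p))
    return out
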