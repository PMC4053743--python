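"""Staining-call rule and marker-association tests for in situ hybridisation.

A tissue core is called positive when at least 30% of tumour cells stain and
negative below 10%; the undefined band [10, 30) is an explicit indeterminate
state excluded from contingency tables. Associations between the binary
staining call and clinical markers (ER, PR, grade, ...) are tested with the
Kruskal-Wallis rank-sum test on the 0/1 calls; with two groups of binary
observations H reduces to ((N-1)/N) times the Pearson chi-square of the
2x2 table, which serves as an independent oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "StainingRecord",
    "ContingencyTable2x2",
    "staining_call",
    "kruskal_wallis",
    "table_from_records",
    "kruskal_from_table",
]

POSITIVE_MIN = 30.0  # percent of cells stained
NEGATIVE_MAX = 10.0


@dataclass(frozen=True)
class StainingRecord:
    """One case's staining readout and clinical covariates."""

    case_id: str
    percent_cells_stained: float
    covariates: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_cells_stained <= 100.0:
            raise ValueError(
                f"{self.case_id}: percent stained must be in [0, 100], "
                f"got {self.percent_cells_stained}"
            )


@dataclass
class ContingencyTable2x2:
    """Staining outcome (positive/negative) by a two-level marker."""

    group_labels: tuple[str, str]
    counts: np.ndarray  # rows = (positive, negative), columns = groups

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (2, 2):
            raise ValueError("counts must be 2x2")
        if (self.counts < 0).any():
            raise ValueError("counts must be >= 0")
        if self.counts.sum() == 0:
            raise ValueError("table is empty")

    def column_percentages(self) -> np.ndarray:
        totals = self.counts.sum(axis=0, keepdims=True)
        return 100.0 * self.counts / np.where(totals == 0, 1, totals)


def staining_call(percent_cells_stained: float) -> str:
    """positive (>=30), negative (<10), or indeterminate ([10, 30))."""
    if not 0.0 <= percent_cells_stained <= 100.0:
        raise ValueError(f"percent stained outside [0, 100]: {percent_cells_stained}")
    if percent_cells_stained >= POSITIVE_MIN:
        return "positive"
    if percent_cells_stained < NEGATIVE_MAX:
        return "negative"
    return "indeterminate"


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p (df = k - 1).

    All-identical observations give (0.0, 1.0).
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def table_from_records(
    records: Sequence[StainingRecord], marker: str, levels: tuple[str, str]
) -> ContingencyTable2x2:
    """Build the 2x2 staining-by-marker table, excluding indeterminate calls.

    Only cases whose ``marker`` covariate equals one of ``levels`` enter the
    table (e.g. grade levels ('1', '3') drop grade-2 tumours).
    """
    counts = np.zeros((2, 2), dtype=int)
    for rec in records:
        level = rec.covariates.get(marker)
        if level not in levels:
            continue
        call = staining_call(rec.percent_cells_stained)
        if call == "indeterminate":
            continue
        counts[0 if call == "positive" else 1, levels.index(level)] += 1
    for j, level in enumerate(levels):
        if counts[:, j].sum() == 0:
            raise ValueError(f"no scorable cases for {marker}={level!r}")
    return ContingencyTable2x2(levels, counts)


def kruskal_from_table(table: ContingencyTable2x2) -> tuple[float, float]:
    """Kruskal-Wallis on the binary staining calls implied by a 2x2 table.

    Each column becomes a group of 1s (positive) and 0s (negative).
    """
    groups = [
        [1.0] * int(table.counts[0, j]) + [0.0] * int(table.counts[1, j])
        for j in range(2)
    ]
    return kruskal_wallis(groups)
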