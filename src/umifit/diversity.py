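"""Clonal diversity statistics evaluated on a per-million-read basis.

Three summaries of a clone table: the number of unique clones, the Shannon
diversity index (entropy of the clone-size distribution, in nats -- a
composite of clone number and evenness), and the area under the Lorenz curve
of cumulative reads against cumulative clones (a function of the size
distribution alone; 0.5 means perfectly even clone sizes).  Because clone
number is not proportional to depth under heavy-tailed size distributions,
"per million reads" is realized as one seeded exact subsample to 1e6 reads
rather than linear rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .clone_extraction import CloneRecord, CloneTable

__all__ = [
    "DiversitySummary",
    "per_million_subsample",
    "shannon_diversity",
    "lorenz_auc",
    "diversity_summary",
]


@dataclass(frozen=True)
class DiversitySummary:
    clones_per_million: int
    sdi_per_million: float
    lorenz_auc: float
    n_reads_used: int
    subsampled: bool


def per_million_subsample(
    table: CloneTable, target_reads: int = 1_000_000, seed: Optional[int] = None
) -> tuple[CloneTable, bool]:
    """Exact multivariate-hypergeometric subsample to ``target_reads`` reads.

    Identity (flag False) when the table is already at or under the target;
    clones drawn to zero are dropped.
    """
    if target_reads < 1:
        raise ValueError("target_reads must be >= 1")
    total = table.total_reads
    if total <= target_reads:
        return table, False
    counts = np.array([r.count for r in table.records], dtype=np.int64)
    rng = np.random.default_rng(seed)
    new_counts = rng.multivariate_hypergeometric(counts, target_reads)
    records = [
        CloneRecord(r.guide_id, r.umi, int(c))
        for r, c in zip(table.records, new_counts)
        if c > 0
    ]
    return CloneTable(sample_id=table.sample_id, records=records), True


def shannon_diversity(table: CloneTable) -> float:
    """Shannon diversity index -sum(p ln p) of clone-size proportions, in nats."""
    if not table.records:
        raise ValueError("empty clone table")
    counts = np.array([r.count for r in table.records], dtype=float)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def lorenz_auc(table: CloneTable) -> float:
    """Area under the Lorenz curve of cumulative reads vs cumulative clones.

    Clones are sorted ascending by size; the piecewise-linear curve runs from
    (0, 0) through (i/n, cumreads_i/total); trapezoidal area, <= 0.5 with
    equality for perfectly even clone sizes.
    """
    if not table.records:
        raise ValueError("empty clone table")
    counts = np.sort(np.array([r.count for r in table.records], dtype=float))
    x = np.arange(len(counts) + 1) / len(counts)
    y = np.concatenate([[0.0], np.cumsum(counts) / counts.sum()])
    return float(np.trapezoid(y, x))


def diversity_summary(
    table: CloneTable, target_reads: int = 1_000_000, seed: Optional[int] = None
) -> DiversitySummary:
    """Clone count, SDI and Lorenz AUC after one per-million subsample."""
    sub, flagged = per_million_subsample(table, target_reads=target_reads, seed=seed)
    return DiversitySummary(
        clones_per_million=len(sub),
        sdi_per_million=shannon_diversity(sub),
        lorenz_auc=lorenz_auc(sub),
        n_reads_used=sub.total_reads,
        subsampled=flagged,
    )
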