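"""Paired-FASTQ to clone table: quality filter, anchored sgRNA/UMI matching,
depth standardization, and directional UMI merging.

The forward amplicon read carries the sgRNA downstream of an invariant vector
anchor; the reverse read carries the degenerate UMI (as the reverse complement
of the forward template) downstream of a second anchor.  Reads sharing one
(sgRNA, UMI) combination form a clone; the read count is the clone size.
Sequencing/PCR errors in UMIs are absorbed afterwards by directional merging:
within each guide, UMI pairs at Hamming distance exactly 1 whose larger count
n_a satisfies n_a > 2*n_b - 1 are connected, and each connected component
collapses to a single clone keeping the UMI of its largest member.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .library_design import LibraryDesign, UmiTemplate, reverse_complement

__all__ = [
    "FORWARD_ANCHOR",
    "REVERSE_ANCHOR",
    "ReadPair",
    "CloneRecord",
    "CloneTable",
    "quality_filter",
    "GuideMatcher",
    "extract_guide",
    "extract_umi",
    "standardize_depth",
    "directional_merge",
    "extract_clones",
    "read_clone_table",
    "write_clone_table",
]

logger = logging.getLogger(__name__)

#: Invariant vector sequence preceding the sgRNA on the forward read.
FORWARD_ANCHOR = "TCTTGTGGAAAGGACGAAACACCG"
#: Invariant vector sequence preceding the UMI on the reverse read.
REVERSE_ANCHOR = "AGCCTCACTGGCCGTCGTTTTACA"

# sgRNA window: 24 to 43 nucleotides downstream of the anchor's last base,
# read as 1-based inclusive offsets (exactly the 20-nt guide length).
_GUIDE_WINDOW = (24, 43)
# UMI search region: 50-nt substring immediately downstream of the reverse anchor.
_UMI_REGION = 50


@dataclass(frozen=True)
class ReadPair:
    """One paired-end record with decoded phred scores."""

    forward_seq: str
    forward_quals: Sequence[int]
    reverse_seq: str
    reverse_quals: Sequence[int]

    def valid_lengths(self) -> bool:
        return len(self.forward_seq) == len(self.forward_quals) and len(
            self.reverse_seq
        ) == len(self.reverse_quals)


@dataclass(frozen=True)
class CloneRecord:
    """One clone: (guide, UMI) identity and its read count (clone size)."""

    guide_id: str
    umi: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"clone ({self.guide_id}, {self.umi}): count {self.count} < 1")
        if len(self.umi) != 27:
            raise ValueError(f"clone ({self.guide_id}): UMI length {len(self.umi)} != 27")


@dataclass
class CloneTable:
    """Per-sample clone records with unique (guide, UMI) keys."""

    sample_id: str
    records: list[CloneRecord]
    stage_counts: Optional[dict] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        keys = [(r.guide_id, r.umi) for r in self.records]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (guide_id, umi) pairs in clone table")

    @property
    def total_reads(self) -> int:
        return sum(r.count for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def counts_by_guide(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for r in self.records:
            out.setdefault(r.guide_id, []).append(r.count)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(self.sample_id, r.guide_id, r.umi, r.count) for r in self.records],
            columns=["sample_id", "guide_id", "umi", "reads"],
        )


def write_clone_table(table: CloneTable, path: "str | Path") -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_clone_table(path: "str | Path", sample_id: Optional[str] = None) -> CloneTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "guide_id": str, "umi": str})
    missing = [c for c in ("guide_id", "umi", "reads") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if sample_id is None:
        sample_id = str(df["sample_id"].iloc[0]) if "sample_id" in df.columns and len(df) else "sample"
    records = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(CloneRecord(str(row.guide_id), str(row.umi), int(row.reads)))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: row {row_no}: {exc}") from exc
    return CloneTable(sample_id=sample_id, records=records)


def quality_filter(
    pairs: Iterable[ReadPair], min_mean_q: float = 30.0
) -> Iterator[ReadPair]:
    """Retain pairs where BOTH mates have mean phred >= min_mean_q.

    Records with mismatched sequence/quality lengths are dropped and logged.
    """
    for pair in pairs:
        if not pair.valid_lengths():
            logger.warning("read pair with seq/qual length mismatch dropped")
            continue
        if (
            sum(pair.forward_quals) / len(pair.forward_quals) >= min_mean_q
            and sum(pair.reverse_quals) / len(pair.reverse_quals) >= min_mean_q
        ):
            yield pair


class GuideMatcher:
    """Mismatch-tolerant lookup of library guides from 20-nt windows."""

    def __init__(self, library: LibraryDesign):
        self._exact = {g.sequence: g.guide_id for g in library.guides}
        self._ids = library.guide_ids
        self._mat = np.frombuffer(
            "".join(library.sequences).encode("ascii"), dtype=np.uint8
        ).reshape(len(library), 20)

    def match(self, window: str, max_mismatch: int = 1) -> Optional[str]:
        hit = self._exact.get(window)
        if hit is not None or max_mismatch == 0:
            return hit
        w = np.frombuffer(window.encode("ascii"), dtype=np.uint8)
        dists = (self._mat != w).sum(axis=1)
        dmin = int(dists.min())
        if dmin > max_mismatch:
            return None
        idx = np.flatnonzero(dists == dmin)
        if len(idx) != 1:  # ambiguous: discard rather than misassign
            return None
        return self._ids[int(idx[0])]


def extract_guide(
    forward_seq: str,
    library: "LibraryDesign | GuideMatcher",
    max_mismatch: int = 1,
) -> Optional[str]:
    """Locate the guide on a forward read; None if unassignable.

    Takes the 20-nt window at offsets 24-43 (1-based, inclusive) downstream of
    the first forward-anchor occurrence and matches it against the library
    exactly, else to the unique nearest guide within ``max_mismatch``.
    """
    if not 1 <= max_mismatch <= 3:
        raise ValueError("max_mismatch must be in 1..3")
    matcher = library if isinstance(library, GuideMatcher) else GuideMatcher(library)
    pos = forward_seq.find(FORWARD_ANCHOR)
    if pos < 0:
        return None
    start = pos + len(FORWARD_ANCHOR) + _GUIDE_WINDOW[0] - 1
    window = forward_seq[start : start + 20]
    if len(window) < 20:
        return None
    return matcher.match(window, max_mismatch)


def _pattern_arrays(template: UmiTemplate) -> tuple[np.ndarray, np.ndarray]:
    # Fixed (non-degenerate) positions of the reverse-complement pattern, as
    # scanned on the reverse read; S positions accept C or G.
    rc = template.reverse_complemented().pattern
    fixed = np.array([c in "ACGT" for c in rc])
    chars = np.frombuffer(rc.encode("ascii"), dtype=np.uint8)
    return fixed, chars


def extract_umi(
    reverse_seq: str,
    template: UmiTemplate,
    max_mismatch: int = 1,
) -> Optional[str]:
    """Locate the UMI on a reverse read; returns it in forward orientation.

    Scans the 50-nt substring after the reverse anchor for the leftmost 27-nt
    window whose fixed positions match the reverse-complement template exactly,
    else the leftmost within ``max_mismatch``; S positions require C/G.  The
    full 27-mer (degenerate positions verbatim) is reverse-complemented to
    forward orientation.
    """
    if not 1 <= max_mismatch <= 3:
        raise ValueError("max_mismatch must be in 1..3")
    pos = reverse_seq.find(REVERSE_ANCHOR)
    if pos < 0:
        return None
    region = reverse_seq[pos + len(REVERSE_ANCHOR) : pos + len(REVERSE_ANCHOR) + _UMI_REGION]
    L = len(template.pattern)
    if len(region) < L:
        return None
    fixed, chars = _pattern_arrays(template)
    rc_pat = template.reverse_complemented().pattern
    arr = np.frombuffer(region.encode("ascii"), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(arr, L)
    mm = (windows[:, fixed] != chars[fixed]).sum(axis=1)
    # S symbols (C/G class): count a mismatch when the base is neither C nor G.
    s_pos = np.array([c == "S" for c in rc_pat])
    if s_pos.any():
        sw = windows[:, s_pos]
        mm = mm + ((sw != ord("C")) & (sw != ord("G"))).sum(axis=1)
    exact = np.flatnonzero(mm == 0)
    if len(exact):
        off = int(exact[0])
    else:
        ok = np.flatnonzero(mm <= max_mismatch)
        if not len(ok):
            return None
        off = int(ok[0])
    return reverse_complement(region[off : off + L])


def standardize_depth(
    records: Sequence, cap: int = 2_000_000, seed: Optional[int] = None
) -> list:
    """Downsample extracted (guide, UMI) reads to at most ``cap`` without
    replacement; identity when under the cap; reproducible under ``seed``."""
    if cap < 1:
        raise ValueError("cap must be >= 1")
    records = list(records)
    if len(records) <= cap:
        return records
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(records), size=cap, replace=False))
    return [records[i] for i in idx]


def _hamming1_pairs(umis: list[str]) -> Iterator[tuple[int, int]]:
    enc = np.frombuffer("".join(umis).encode("ascii"), dtype=np.uint8).reshape(
        len(umis), len(umis[0])
    )
    # All-pairs in chunks; clone counts per guide are modest after dedup.
    n = len(umis)
    chunk = max(1, 2_000_000 // max(n, 1))
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        d = (enc[lo:hi, None, :] != enc[None, :, :]).sum(axis=2)
        for a, b in zip(*np.nonzero(d == 1)):
            ia = lo + int(a)
            if ia < int(b):
                yield ia, int(b)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def directional_merge(table: CloneTable) -> CloneTable:
    """Collapse sequencing-error UMIs within each guide.

    Edges connect UMI pairs at Hamming distance exactly 1 whose counts (taken
    from the pre-merge table) satisfy n_a > 2*n_b - 1 with n_a the larger.
    Each connected component becomes one clone with the summed count and the
    UMI of the largest member (ties broken to the lexicographically smallest
    UMI).  Total reads are conserved.
    """
    by_guide: dict[str, list[CloneRecord]] = {}
    for r in table.records:
        by_guide.setdefault(r.guide_id, []).append(r)
    merged: list[CloneRecord] = []
    for guide_id, recs in by_guide.items():
        if len(recs) == 1:
            merged.append(recs[0])
            continue
        umis = [r.umi for r in recs]
        counts = [r.count for r in recs]
        uf = _UnionFind(len(recs))
        for a, b in _hamming1_pairs(umis):
            na, nb = max(counts[a], counts[b]), min(counts[a], counts[b])
            if na > 2 * nb - 1:
                uf.union(a, b)
        comps: dict[int, list[int]] = {}
        for i in range(len(recs)):
            comps.setdefault(uf.find(i), []).append(i)
        for members in comps.values():
            total = sum(counts[i] for i in members)
            rep = min(members, key=lambda i: (-counts[i], umis[i]))
            merged.append(CloneRecord(guide_id, umis[rep], total))
    out = CloneTable(sample_id=table.sample_id, records=merged)
    assert out.total_reads == table.total_reads
    return out


def _read_fastq_pairs(fastq_fwd, fastq_rev) -> Iterator[ReadPair]:
    import pysam

    with pysam.FastxFile(str(fastq_fwd)) as f1, pysam.FastxFile(str(fastq_rev)) as f2:
        for fwd, rev in zip(f1, f2):
            yield ReadPair(
                fwd.sequence,
                fwd.get_quality_array(),
                rev.sequence,
                rev.get_quality_array(),
            )


def extract_clones(
    fastq_fwd: "str | Path",
    fastq_rev: "str | Path",
    library: LibraryDesign,
    max_mismatch: int = 1,
    min_mean_q: float = 30.0,
    cap: int = 2_000_000,
    seed: Optional[int] = None,
    sample_id: str = "sample",
) -> CloneTable:
    """Full extraction pipeline; stage counts are attached as ``stage_counts``.

    quality filter -> guide/UMI extraction (pairs failing either are dropped)
    -> depth standardization -> (guide, UMI) tally -> directional merge.
    """
    matcher = GuideMatcher(library)
    template = library.umi_template
    stage = {"pairs_in": 0, "pass_quality": 0, "assigned": 0}

    def assigned_stream():
        for pair in _read_fastq_pairs(fastq_fwd, fastq_rev):
            stage["pairs_in"] += 1
            if not pair.valid_lengths():
                continue
            if (
                sum(pair.forward_quals) / max(len(pair.forward_quals), 1) < min_mean_q
                or sum(pair.reverse_quals) / max(len(pair.reverse_quals), 1) < min_mean_q
            ):
                continue
            stage["pass_quality"] += 1
            guide = extract_guide(pair.forward_seq, matcher, max_mismatch)
            if guide is None:
                continue
            umi = extract_umi(pair.reverse_seq, template, max_mismatch)
            if umi is None:
                continue
            stage["assigned"] += 1
            yield (guide, umi)

    kept = standardize_depth(list(assigned_stream()), cap=cap, seed=seed)
    stage["after_downsampling"] = len(kept)
    tally: dict[tuple[str, str], int] = {}
    for key in kept:
        tally[key] = tally.get(key, 0) + 1
    records = [CloneRecord(g, u, c) for (g, u), c in tally.items()]
    stage["clones_raw"] = len(records)
    table = CloneTable(sample_id=sample_id, records=records)
    if records:
        table = directional_merge(table)
    stage["clones_merged"] = len(table)
    logger.info("extract_clones %s: %s", sample_id, stage)
    table.stage_counts = stage
    return table
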