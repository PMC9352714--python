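"""Guide libraries and the degenerate UMI barcode template.

A pooled screen library is a set of 20-nt sgRNA targeting sequences, each
tagged with a target gene and a control class, co-delivered with a partially
degenerate UMI barcode so that every transduced founder cell receives a
(near-)unique clone label.  This module holds the library containers, the
IUPAC template arithmetic, table IO, and deterministic synthetic fixture
libraries mirroring the two screen designs used throughout the package
(a 192-guide signaling library and a 128-guide Notch-pathway library).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "GuideRecord",
    "UmiTemplate",
    "LibraryDesign",
    "DEFAULT_UMI_PATTERN",
    "GUIDE_CLASSES",
    "template_cardinality",
    "reverse_complement",
    "load_library",
    "write_library",
    "make_fixture",
    "make_random_library",
]

#: Forward-orientation degenerate UMI barcode pattern (N = A/C/G/T, S = C/G).
DEFAULT_UMI_PATTERN = "NNATCNNGATSSAAANNGGTNNAACNN"

GUIDE_CLASSES = ("targeting", "non_targeting", "non_gene_targeting")

_DEGENERACY = {"A": 1, "C": 1, "G": 1, "T": 1, "N": 4, "S": 2}
_EXPANSION = {"A": "A", "C": "C", "G": "G", "T": "T", "N": "ACGT", "S": "CG"}
_COMPLEMENT = str.maketrans("ACGTNS", "TGCANS")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def reverse_complement(seq: str) -> str:
    """Reverse-complement a DNA string; degenerate N and S are self-complementary classes."""
    return seq.translate(_COMPLEMENT)[::-1]


def template_cardinality(template: "UmiTemplate | str") -> int:
    """Number of distinct concrete DNA sequences matching an IUPAC pattern.

    The product of per-position degeneracies (N contributes 4, S contributes
    2, concrete bases 1); exact integer arithmetic.
    """
    pattern = template.pattern if isinstance(template, UmiTemplate) else template
    n = 1
    for i, sym in enumerate(pattern):
        if sym not in _DEGENERACY:
            raise ValueError(f"unknown IUPAC symbol {sym!r} at position {i} in template")
        n *= _DEGENERACY[sym]
    return n


@dataclass(frozen=True)
class GuideRecord:
    """One sgRNA: id, 20-nt targeting sequence, target gene, control class."""

    guide_id: str
    sequence: str
    gene: Optional[str] = None
    guide_class: str = "targeting"

    def __post_init__(self) -> None:
        if len(self.sequence) != 20:
            raise ValueError(
                f"guide {self.guide_id!r}: sequence length {len(self.sequence)} != 20"
            )
        if set(self.sequence) - set("ACGT"):
            raise ValueError(f"guide {self.guide_id!r}: non-ACGT characters in sequence")
        if self.guide_class not in GUIDE_CLASSES:
            raise ValueError(
                f"guide {self.guide_id!r}: guide_class {self.guide_class!r} "
                f"not one of {GUIDE_CLASSES}"
            )

    @property
    def is_targeting(self) -> bool:
        return self.guide_class == "targeting"


@dataclass(frozen=True)
class UmiTemplate:
    """Degenerate UMI pattern with an orientation tag.

    ``forward`` is the orientation in which UMIs are reported; the reverse
    sequencing read carries the reverse complement of the template.
    """

    pattern: str = DEFAULT_UMI_PATTERN
    orientation: str = "forward"

    def __post_init__(self) -> None:
        if set(self.pattern) - set(_DEGENERACY):
            bad = sorted(set(self.pattern) - set(_DEGENERACY))
            raise ValueError(f"template contains unsupported symbols {bad}")
        if self.orientation not in ("forward", "reverse_complement"):
            raise ValueError(f"bad orientation {self.orientation!r}")

    def __len__(self) -> int:
        return len(self.pattern)

    def reverse_complemented(self) -> "UmiTemplate":
        other = (
            "reverse_complement" if self.orientation == "forward" else "forward"
        )
        return UmiTemplate(reverse_complement(self.pattern), other)

    def cardinality(self) -> int:
        return template_cardinality(self.pattern)

    def matches(self, window: str, max_mismatch: int = 0) -> bool:
        """True if ``window`` matches the pattern's fixed positions within ``max_mismatch``."""
        if len(window) != len(self.pattern):
            return False
        mm = 0
        for sym, base in zip(self.pattern, window):
            if base not in _EXPANSION[sym]:
                mm += 1
                if mm > max_mismatch:
                    return False
        return True

    def realize(self, rng: np.random.Generator) -> str:
        """Draw one concrete sequence uniformly from the template."""
        return "".join(
            _EXPANSION[sym][rng.integers(len(_EXPANSION[sym]))] for sym in self.pattern
        )


@dataclass
class LibraryDesign:
    """A named guide library plus its UMI template."""

    name: str
    guides: list[GuideRecord]
    umi_template: UmiTemplate = field(default_factory=UmiTemplate)

    def __post_init__(self) -> None:
        if not self.guides:
            raise ValueError("library must contain at least one guide")
        ids = [g.guide_id for g in self.guides]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate guide ids: {dupes}")
        seqs = [g.sequence for g in self.guides]
        if len(set(seqs)) != len(seqs):
            raise ValueError("duplicate guide sequences in library")
        self._by_id = {g.guide_id: g for g in self.guides}
        self._by_seq = {g.sequence: g.guide_id for g in self.guides}

    def __len__(self) -> int:
        return len(self.guides)

    def __getitem__(self, guide_id: str) -> GuideRecord:
        return self._by_id[guide_id]

    def __contains__(self, guide_id: str) -> bool:
        return guide_id in self._by_id

    @property
    def guide_ids(self) -> list[str]:
        return [g.guide_id for g in self.guides]

    @property
    def sequences(self) -> list[str]:
        return [g.sequence for g in self.guides]

    def guide_by_sequence(self, seq: str) -> Optional[str]:
        return self._by_seq.get(seq)

    def targeting_ids(self) -> list[str]:
        return [g.guide_id for g in self.guides if g.is_targeting]

    def control_ids(self) -> list[str]:
        return [g.guide_id for g in self.guides if not g.is_targeting]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dataclasses.asdict(g) for g in self.guides],
            columns=["guide_id", "sequence", "gene", "guide_class"],
        )


_REQUIRED_COLUMNS = ["guide_id", "sequence", "gene", "guide_class"]


def load_library(
    path: "str | Path",
    name: Optional[str] = None,
    umi_template: Optional[UmiTemplate] = None,
) -> LibraryDesign:
    """Load a library design table (TSV or CSV by extension).

    Required columns: guide_id, sequence, gene, guide_class.  Row-level
    validation errors report the offending row number.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    guides = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        gene = None if pd.isna(row.gene) or row.gene == "" else str(row.gene)
        try:
            guides.append(
                GuideRecord(str(row.guide_id), str(row.sequence), gene, str(row.guide_class))
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {row_no}: {exc}") from exc
    return LibraryDesign(
        name=name or path.stem,
        guides=guides,
        umi_template=umi_template or UmiTemplate(),
    )


def write_library(design: LibraryDesign, path: "str | Path") -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    design.to_frame().to_csv(path, sep=sep, index=False)


def _random_sequences(n: int, rng: np.random.Generator, min_hamming: int = 3) -> list[str]:
    # Rejection sampling keeps pairwise Hamming distance >= min_hamming so that
    # 1-mismatch read matching is unambiguous by construction.
    kept = np.empty((0, 20), dtype=np.uint8)
    out: list[str] = []
    while len(out) < n:
        cand = _BASES[rng.integers(0, 4, size=20)]
        if kept.size and int((kept != cand).sum(axis=1).min()) < min_hamming:
            continue
        kept = np.vstack([kept, cand])
        out.append(cand.tobytes().decode("ascii"))
    return out


def make_random_library(
    n_targeting: int,
    n_control: int,
    guides_per_gene: int = 3,
    seed: int = 0,
    name: str = "random",
) -> LibraryDesign:
    """Synthetic library with ``n_targeting`` gene-targeting guides grouped into
    genes of ``guides_per_gene`` plus ``n_control`` non-targeting controls."""
    rng = np.random.default_rng(seed)
    seqs = _random_sequences(n_targeting + n_control, rng)
    guides = []
    for i in range(n_targeting):
        gene_no, within = divmod(i, guides_per_gene)
        guides.append(
            GuideRecord(
                f"gene{gene_no + 1:03d}_{within + 1}",
                seqs[i],
                gene=f"gene{gene_no + 1:03d}",
                guide_class="targeting",
            )
        )
    for i in range(n_control):
        guides.append(
            GuideRecord(
                f"nt_{i + 1:02d}", seqs[n_targeting + i], gene=None, guide_class="non_targeting"
            )
        )
    return LibraryDesign(name=name, guides=guides)


# Fixture composition mirrors the two screen designs: 56 genes in guide
# triplicate plus 24 non-targeting controls (192 total), and 26 Notch-pathway
# genes with 4 guides each plus 24 non-targeting controls (128 total).
# Sequences are synthetic (seeded, bit-stable), not real guide designs.
_FIXTURES = {
    "signaling": dict(n_genes=56, guides_per_gene=3, n_control=24, seed=20220527),
    "notch": dict(n_genes=26, guides_per_gene=4, n_control=24, seed=20220528),
}


def make_fixture(name: str) -> LibraryDesign:
    """Deterministic synthetic fixture library: ``signaling`` (192 guides) or
    ``notch`` (128 guides)."""
    if name not in _FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}")
    cfg = _FIXTURES[name]
    lib = make_random_library(
        n_targeting=cfg["n_genes"] * cfg["guides_per_gene"],
        n_control=cfg["n_control"],
        guides_per_gene=cfg["guides_per_gene"],
        seed=cfg["seed"],
        name=name,
    )
    return lib
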