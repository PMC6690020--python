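"""Genomic interval primitives and overlap queries.

All in-memory coordinates are 0-based half-open (``[start, end)``), the BED
convention. Readers convert at the parse boundary; writers convert back where a
format demands it. Keeping a single convention internally avoids the silent
mixing of UCSC-table, BED, and 1-based report coordinates that plagues ad-hoc
methylome scripts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

VALID_STRANDS = ("+", "-", ".")

#: Closed vocabulary of repeat classes; anything else maps to ``Other``.
REPEAT_CLASSES = (
    "LINE",
    "SINE",
    "LTR",
    "Simple_repeat",
    "Low_complexity",
    "Satellite",
    "DNA",
    "Other",
)


def normalize_strand(symbol: str) -> str:
    """Map strand spellings (including the typographic minus) onto ``+ - .``."""
    s = symbol.strip()
    if s in ("−", "C"):  # unicode minus; RepeatMasker uses C for complement
        return "-"
    if s in VALID_STRANDS:
        return s
    raise ValueError(f"invalid strand symbol: {symbol!r}")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    start, end : int
        0-based half-open bounds; ``0 <= start < end`` is enforced.
    strand : str
        One of ``+``, ``-``, ``.`` (default unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        object.__setattr__(self, "strand", normalize_strand(self.strand))

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_pos(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand and exon structure.

    The transcription start site (TSS) and the first exon are strand-aware:
    on ``+`` the TSS is ``tx_start`` and the first exon the leftmost exon; on
    ``-`` the TSS is ``tx_end - 1`` and the first exon the rightmost.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[GenomicInterval, ...] = field(default=())

    def __post_init__(self) -> None:
        strand = normalize_strand(self.strand)
        if strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        object.__setattr__(self, "strand", strand)
        if not (0 <= self.tx_start < self.tx_end):
            raise ValueError(f"gene {self.gene_id}: invalid transcript bounds")
        exons = tuple(self.exons)
        prev_end = None
        for ex in exons:
            if ex.chrom != self.chrom:
                raise ValueError(f"gene {self.gene_id}: exon on wrong chromosome")
            if ex.start < self.tx_start or ex.end > self.tx_end:
                raise ValueError(f"gene {self.gene_id}: exon outside transcript")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(
                    f"gene {self.gene_id}: exons must be sorted and non-overlapping"
                )
            prev_end = ex.end
        object.__setattr__(self, "exons", exons)

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def first_exon(self) -> GenomicInterval | None:
        if not self.exons:
            return None
        return self.exons[0] if self.strand == "+" else self.exons[-1]

    @property
    def body(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.tx_start, self.tx_end, self.strand)


@dataclass(frozen=True)
class RepeatElement:
    """One RepeatMasker-annotated repeat copy."""

    interval: GenomicInterval
    rep_name: str
    rep_class: str
    rep_family: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "rep_class", normalize_repeat_class(self.rep_class))


def normalize_repeat_class(raw: str) -> str:
    """Map a raw repClass string onto the closed repeat-class vocabulary.

    Uncertainty suffixes (``SINE?``) are stripped; ``class/family`` compounds
    keep the class part; anything unrecognised becomes ``Other`` with a
    warning.
    """
    cls = raw.strip().rstrip("?").split("/", 1)[0]
    if cls in REPEAT_CLASSES:
        return cls
    warnings.warn(f"unknown repeat class {raw!r}; mapping to Other", stacklevel=2)
    return "Other"


class IntervalIndex:
    """Per-chromosome interval tree supporting point and interval overlap queries."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._trees: dict[str, IntervalTree] = {}
        n = 0
        for iv in intervals:
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
            n += 1
        self._n = n

    def __len__(self) -> int:
        return self._n

    def overlapping(self, chrom: str, start: int, end: int) -> list[GenomicInterval]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(start, end)]

    def any_overlap(self, chrom: str, start: int, end: int) -> bool:
        tree = self._trees.get(chrom)
        return tree is not None and bool(tree.overlap(start, end))

    def covers_points(self, chroms: Sequence[str], positions: np.ndarray) -> np.ndarray:
        """Vectorised point-in-any-interval test; returns a boolean array."""
        out = np.zeros(len(positions), dtype=bool)
        for i, (chrom, pos) in enumerate(zip(chroms, positions)):
            tree = self._trees.get(chrom)
            if tree is not None and tree.overlaps_point(int(pos)):
                out[i] = True
        return out

    @property
    def chromosomes(self) -> set[str]:
        return set(self._trees)
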