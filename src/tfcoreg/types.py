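"""Core domain types shared by every pipeline stage.

All genomic coordinates in this package are 0-based, half-open (the BED
convention): an interval ``[start, end)`` covers ``end - start`` bases and
``start == end`` is empty (and invalid).  Human-readable reports print
1-based inclusive positions; the two converters at the bottom of this
module are the only place the conversion happens.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval; the unit of peaks, reads, excluded
    regions and gene features."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval", min_overlap_bp: int = 1) -> bool:
        if self.chrom != other.chrom:
            return False
        return min(self.end, other.end) - max(self.start, other.start) >= min_overlap_bp


@dataclass
class GeneModel:
    """Gene structure: TSS, span and exons; introns are derived, never read.

    The TSS equals ``gene_start`` on the + strand and ``gene_end - 1`` on
    the - strand.  Exons must be sorted, non-overlapping and inside the span.
    """

    gene_id: str
    chrom: str
    strand: str
    gene_start: int
    gene_end: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        if not (0 <= self.gene_start < self.gene_end):
            raise ValueError(f"invalid gene span for {self.gene_id}")
        prev_end = self.gene_start
        for s, e in self.exons:
            if s < prev_end or e > self.gene_end or s >= e:
                raise ValueError(
                    f"exons of {self.gene_id} must be sorted, non-overlapping "
                    "and inside the gene span"
                )
            prev_end = e

    @property
    def tss(self) -> int:
        return self.gene_start if self.strand == "+" else self.gene_end - 1

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons (empty when < 2 exons)."""
        out = []
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if s1 > e0:
                out.append((e0, s1))
        return out

    def signed_distance_to_tss(self, position: int) -> int:
        """Signed bp from TSS to ``position``; positive downstream in gene
        orientation, negative upstream."""
        d = position - self.tss
        return d if self.strand == "+" else -d


class FoldChangeTable:
    """Genes x experiments matrix of log fold-changes relative to matched
    controls.

    Thin wrapper over a pandas DataFrame (genes as index, experiment ids as
    columns) that enforces uniqueness and finiteness at construction.
    """

    def __init__(self, values, gene_ids=None, experiment_ids=None):
        if isinstance(values, pd.DataFrame):
            df = values.copy()
        else:
            df = pd.DataFrame(np.asarray(values, dtype=float),
                              index=list(gene_ids), columns=list(experiment_ids))
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if df.shape[1] < 1:
            raise ValueError("need at least one experiment column")
        arr = df.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite fold-change at gene {df.index[i]!r}, "
                f"experiment {df.columns[j]!r}"
            )
        self.frame = df

    @property
    def gene_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def experiment_ids(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.frame.shape[0]

    @property
    def n_experiments(self) -> int:
        return self.frame.shape[1]

    def __eq__(self, other) -> bool:
        return isinstance(other, FoldChangeTable) and self.frame.equals(other.frame)


class ReadStartTrack:
    """Per-chromosome sorted read 5'-start positions with total depth."""

    def __init__(self, positions: dict[str, np.ndarray], chrom_lengths: dict[str, int]):
        self.positions: dict[str, np.ndarray] = {}
        self.chrom_lengths = dict(chrom_lengths)
        for chrom, pos in positions.items():
            arr = np.sort(np.asarray(pos, dtype=np.int64))
            L = self.chrom_lengths.get(chrom)
            if L is None:
                raise ValueError(f"no length for chromosome {chrom!r}")
            if arr.size and (arr[0] < 0 or arr[-1] >= L):
                raise ValueError(f"read positions outside [0, {L}) on {chrom}")
            self.positions[chrom] = arr

    @property
    def total_depth(self) -> int:
        return int(sum(p.size for p in self.positions.values()))

    @property
    def genome_length(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    def count_in(self, chrom: str, start: int, end: int) -> int:
        """Number of read starts with position in [start, end)."""
        pos = self.positions.get(chrom)
        if pos is None:
            return 0
        return int(np.searchsorted(pos, end, "left") - np.searchsorted(pos, start, "left"))


def to_one_based(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive (for human-readable reports)."""
    return start0 + 1, end0


def to_zero_based(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open; inverse of :func:`to_one_based`."""
    return start1 - 1, end1
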