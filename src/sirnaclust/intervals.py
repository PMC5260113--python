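"""Genomic coordinate primitives.

All coordinates inside the package are 0-based half-open ``[start, end)``.
File formats using other conventions (GFF3: 1-based inclusive) are converted
at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval ``[start, end)`` anchored to a chromosome.

    ``strand`` is ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def jaccard(self, other: "GenomicInterval") -> float:
        inter = self.overlap_length(other)
        if inter == 0:
            return 0.0
        union = self.length() + other.length() - inter
        return inter / union

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset, self.strand)


class IntervalIndex:
    """Chromosome-partitioned interval tree for overlap queries."""

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self._n = 0  # per-entry sequence number so duplicates survive set semantics
        for iv in intervals:
            self.add(iv)

    def add(self, interval: GenomicInterval, payload=None) -> None:
        tree = self._trees.setdefault(interval.chrom, IntervalTree())
        tree.addi(interval.start, interval.end, (self._n, interval, payload))
        self._n += 1

    def overlapping(self, query: GenomicInterval) -> list[GenomicInterval]:
        """All stored intervals with >= 1 bp overlap with ``query``."""
        return [iv for iv, _ in self.overlapping_items(query)]

    def overlapping_items(self, query: GenomicInterval) -> list[tuple[GenomicInterval, object]]:
        tree = self._trees.get(query.chrom)
        if tree is None:
            return []
        hits = sorted(tree.overlap(query.start, query.end), key=lambda h: (h.begin, h.end, h.data[0]))
        return [(h.data[1], h.data[2]) for h in hits]

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())


def overlap_query(
    intervals: Iterable[GenomicInterval] | IntervalIndex, query: GenomicInterval
) -> list[GenomicInterval]:
    """Return exactly the intervals sharing >= 1 bp with ``query``.

    Accepts either a pre-built :class:`IntervalIndex` or any iterable of
    intervals (indexed on the fly).
    """
    index = intervals if isinstance(intervals, IntervalIndex) else IntervalIndex(intervals)
    return index.overlapping(query)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Sweep-line union: transitively merge intervals sharing >= 1 bp.

    Book-ended intervals ([0,100) and [100,200)) share zero bases and are
    not merged. Output is sorted and pairwise disjoint.
    """
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end, last.strand)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end, iv.strand))
    return merged


@dataclass
class GenomeLayout:
    """Chromosome sizes plus centromere coordinates."""

    chrom_sizes: dict[str, int] = field(default_factory=dict)
    centromeres: dict[str, GenomicInterval] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, cen in self.centromeres.items():
            size = self.chrom_sizes.get(chrom)
            if size is None:
                raise ValueError(f"centromere given for unknown chromosome {chrom!r}")
            if cen.end > size:
                raise ValueError(
                    f"centromere {cen} exceeds chromosome length {size} on {chrom}"
                )

    def chroms(self) -> Iterator[str]:
        return iter(sorted(self.chrom_sizes))

    # -- TSV I/O -------------------------------------------------------
    @classmethod
    def from_tsv(cls, sizes_path: str | Path, centromeres_path: str | Path | None = None) -> "GenomeLayout":
        sizes_df = pd.read_csv(sizes_path, sep="\t", header=None, names=["chrom", "length"])
        sizes = dict(zip(sizes_df["chrom"].astype(str), sizes_df["length"].astype(int)))
        cens: dict[str, GenomicInterval] = {}
        if centromeres_path is not None:
            cen_df = pd.read_csv(
                centromeres_path, sep="\t", header=None, names=["chrom", "start", "end"]
            )
            for row in cen_df.itertuples(index=False):
                cens[str(row.chrom)] = GenomicInterval(str(row.chrom), int(row.start), int(row.end))
        return cls(chrom_sizes=sizes, centromeres=cens)

    def to_tsv(self, sizes_path: str | Path, centromeres_path: str | Path | None = None) -> None:
        with open(sizes_path, "w") as fh:
            for chrom in sorted(self.chrom_sizes):
                fh.write(f"{chrom}\t{self.chrom_sizes[chrom]}\n")
        if centromeres_path is not None:
            with open(centromeres_path, "w") as fh:
                for chrom in sorted(self.centromeres):
                    cen = self.centromeres[chrom]
                    fh.write(f"{chrom}\t{cen.start}\t{cen.end}\n")
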