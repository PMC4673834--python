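"""Genome model, genomic intervals and per-base signal tracks.

Coordinates are 0-based, half-open throughout (BED native). Coverage and
occupancy tracks are dense per-base numpy vectors, one per chromosome;
the genomes this package targets are desk-scale (a few tens of Mb), so a
dense representation keeps every per-base operation exact and trivially
testable against brute-force oracles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


class FormatError(ValueError):
    """Malformed input file or invariant-violating record."""


class GenomeIndex:
    """Ordered map of chromosome name -> length in bp.

    Chromosome order is the insertion order and is stable for a run;
    every coordinate consumed by the package is validated against it.
    """

    def __init__(self, items: Iterable[tuple[str, int]] = ()):
        self._lengths: dict[str, int] = {}
        for name, length in items:
            self.add(str(name), int(length))

    def add(self, name: str, length: int) -> None:
        if name in self._lengths:
            raise FormatError(f"duplicate chromosome name {name!r}")
        if length <= 0:
            raise FormatError(f"non-positive length {length} for chromosome {name!r}")
        self._lengths[name] = length

    @property
    def names(self) -> list[str]:
        return list(self._lengths)

    def __len__(self) -> int:
        return len(self._lengths)

    def __contains__(self, name: str) -> bool:
        return name in self._lengths

    def __getitem__(self, name: str) -> int:
        return self._lengths[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._lengths)

    def items(self):
        return self._lengths.items()

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeIndex) and list(self.items()) == list(other.items())

    def __repr__(self) -> str:
        return f"GenomeIndex({len(self)} chromosomes, {self.total_size} bp)"

    @property
    def total_size(self) -> int:
        return sum(self._lengths.values())

    def require(self, chrom: str) -> int:
        if chrom not in self._lengths:
            raise FormatError(f"unknown chromosome {chrom!r}")
        return self._lengths[chrom]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise FormatError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def check_in(self, genome: GenomeIndex) -> "GenomicInterval":
        if self.end > genome.require(self.chrom):
            raise FormatError(
                f"interval {self.chrom}:{self.start}-{self.end} exceeds "
                f"chromosome length {genome[self.chrom]}"
            )
        return self

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class ReadAlignment:
    """A mapped sequencing read; only uniquely mapped reads enter coverage."""

    interval: GenomicInterval
    unique: bool = True


def _group_by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append(iv)
    return out


@dataclass
class CoverageTrack:
    """Per-base non-negative signal, one float vector per chromosome."""

    genome: GenomeIndex
    data: dict[str, np.ndarray]
    n_reads: int | None = None

    @classmethod
    def zeros(cls, genome: GenomeIndex, dtype=np.float64) -> "CoverageTrack":
        return cls(genome, {c: np.zeros(genome[c], dtype=dtype) for c in genome})

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.data[chrom]

    def total(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def validate(self) -> None:
        for chrom in self.genome:
            v = self.data[chrom]
            if len(v) != self.genome[chrom]:
                raise ValueError(f"track length mismatch on {chrom}")
            if np.any(v < 0):
                raise ValueError(f"negative signal on {chrom}")


@dataclass
class BinaryTrack:
    """Per-base 0/1 occupancy indicator, one vector per chromosome."""

    genome: GenomeIndex
    data: dict[str, np.ndarray]

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.data[chrom]


def extend_reads(
    reads: Iterable[ReadAlignment | GenomicInterval],
    genome: GenomeIndex,
    length: int = 200,
) -> list[GenomicInterval]:
    """Extend each uniquely mapped read to `length` bp in its 3' direction.

    Plus-strand (and unstranded) reads keep their 5' start and grow rightward;
    minus-strand reads keep their 3'-most coordinate (the interval end) and
    grow leftward. Extended intervals are clipped to chromosome bounds.
    Non-unique alignments are dropped (with a logged count).
    """
    out: list[GenomicInterval] = []
    n_dropped = 0
    for read in reads:
        if isinstance(read, ReadAlignment):
            if not read.unique:
                n_dropped += 1
                continue
            iv = read.interval
        else:
            iv = read
        chrom_len = genome.require(iv.chrom)
        if iv.strand == "-":
            start, end = iv.end - length, iv.end
        else:
            start, end = iv.start, iv.start + length
        start = max(0, start)
        end = min(chrom_len, end)
        out.append(GenomicInterval(iv.chrom, start, end, iv.strand))
    if n_dropped:
        logger.info("extend_reads: dropped %d non-uniquely mapped reads", n_dropped)
    return out


def coverage_from_intervals(
    intervals: Iterable[GenomicInterval], genome: GenomeIndex
) -> CoverageTrack:
    """Per-base count of intervals covering each position (read pileup)."""
    by_chrom = _group_by_chrom(intervals)
    data: dict[str, np.ndarray] = {}
    n = 0
    for chrom in genome:
        L = genome[chrom]
        ivs = by_chrom.pop(chrom, [])
        n += len(ivs)
        if not ivs:
            data[chrom] = np.zeros(L, dtype=np.float64)
            continue
        starts = np.array([iv.check_in(genome).start for iv in ivs])
        ends = np.array([iv.end for iv in ivs])
        delta = np.bincount(starts, minlength=L + 1).astype(np.int64)
        delta -= np.bincount(ends, minlength=L + 1)
        data[chrom] = np.cumsum(delta[:-1]).astype(np.float64)
    if by_chrom:
        raise FormatError(f"intervals on unknown chromosomes: {sorted(by_chrom)}")
    return CoverageTrack(genome, data, n_reads=n)


def binarize_occupancy(
    peaks: Iterable[GenomicInterval], genome: GenomeIndex
) -> BinaryTrack:
    """1 at every base covered by at least one peak, else 0."""
    cov = coverage_from_intervals(peaks, genome)
    return BinaryTrack(
        genome, {c: (cov[c] > 0).astype(np.uint8) for c in genome}
    )


class ReadIndex:
    """Sorted per-chromosome read intervals supporting O(log n) overlap counts.

    A read counts once per region if it overlaps the region by >= 1 bp.
    """

    def __init__(self, intervals: Iterable[GenomicInterval], genome: GenomeIndex):
        self.genome = genome
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self.n_reads = 0
        by_chrom = _group_by_chrom(intervals)
        for chrom, ivs in by_chrom.items():
            genome.require(chrom)
            self._starts[chrom] = np.sort(np.array([iv.start for iv in ivs]))
            self._ends[chrom] = np.sort(np.array([iv.end for iv in ivs]))
            self.n_reads += len(ivs)

    def count(self, region: GenomicInterval) -> int:
        """Number of reads overlapping [start, end) by at least one base."""
        if region.chrom not in self._starts:
            return 0
        starts = self._starts[region.chrom]
        ends = self._ends[region.chrom]
        n_start_before_end = int(np.searchsorted(starts, region.end, side="left"))
        n_end_before_start = int(np.searchsorted(ends, region.start, side="right"))
        return n_start_before_end - n_end_before_start
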