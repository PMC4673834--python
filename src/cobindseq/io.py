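"""Readers and writers for chrom.sizes, BED, bedGraph and FASTA.

All formats here are plain text and deterministic byte-for-byte given
fixed inputs. Parsers validate against a GenomeIndex and raise
FormatError naming the offending line.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .genome import (
    CoverageTrack,
    FormatError,
    GenomeIndex,
    GenomicInterval,
)


def read_chrom_sizes(path: str | Path) -> GenomeIndex:
    """Parse a two-column (name, length) chromosome sizes file."""
    genome = GenomeIndex()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            name, length_str = fields
            try:
                length = int(length_str)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer length {length_str!r}") from None
            try:
                genome.add(name, length)
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return genome


def read_bed(path: str | Path, genome: GenomeIndex) -> list[GenomicInterval]:
    """Parse BED3-BED6 into intervals, in file order; strand '.' if absent."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                iv = GenomicInterval(chrom, start, end, strand).check_in(genome)
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            intervals.append(iv)
    return intervals


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> None:
    """Write intervals as BED6. Default names are site_1..site_n, score 0."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"site_{i + 1}"
            score = scores[i] if scores is not None else 0
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n")


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a coverage track as bedGraph with maximal constant-value runs.

    Zero runs are omitted so that read(write(x)) round-trips exactly at
    1-bp resolution.
    """
    with open(path, "w") as fh:
        for chrom in track.genome:
            values = track[chrom]
            if len(values) == 0:
                continue
            change = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(values)]))
            for s, e in zip(starts, ends):
                v = values[s]
                if v == 0:
                    continue
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_bedgraph(path: str | Path, genome: GenomeIndex) -> CoverageTrack:
    track = CoverageTrack.zeros(genome)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, start, end, value = fields
            try:
                s, e, v = int(start), int(end), float(value)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: malformed bedGraph fields") from None
            if chrom not in genome or not (0 <= s < e <= genome[chrom]):
                raise FormatError(f"{path}:{lineno}: coordinates outside genome")
            track[chrom][s:e] = v
    return track


def write_fasta(
    sequences: dict[str, str | bytes],
    path: str | Path,
    line_width: int = 60,
) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            if isinstance(seq, bytes):
                seq = seq.decode("ascii")
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")
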