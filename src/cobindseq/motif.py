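"""Composite-motif scanning over binding-site sequences.

The default pattern is the bipartite E-box/GATA signature of the LDB1
transcription-factor complex, CTG N(6-8) WGATAR: a CTG E-box core, an
unconstrained spacer of 6-8 bp, and the WGATAR GATA consensus. Scanning
is IUPAC-aware, case-insensitive and strand-symmetric (minus-strand hits
are found by matching the reverse complement of the pattern on the
forward sequence and reported in forward coordinates). Site preparation
follows the standard recipe: 200-bp sequences centered on each site,
removal of sites with >= 150 bp of repeat-masked (lowercase/N) sequence,
and optional uniform subsampling for large classes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    # An N in the subject sequence matches only a pattern N; this keeps
    # masked N-runs from producing spurious composite hits.
    "N": frozenset("ACGTN"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(iupac: str) -> str:
    return iupac.upper().translate(_COMPLEMENT)[::-1]


def _check_iupac(s: str, what: str) -> str:
    s = s.upper()
    bad = set(s) - set(IUPAC)
    if bad:
        raise ValueError(f"invalid IUPAC code(s) {sorted(bad)} in {what}")
    return s


@dataclass(frozen=True)
class MotifPattern:
    """Bipartite IUPAC pattern: left part, N-spacer range, right part."""

    left: str
    spacer_min: int
    spacer_max: int
    right: str

    def __post_init__(self):
        object.__setattr__(self, "left", _check_iupac(self.left, "left part"))
        object.__setattr__(self, "right", _check_iupac(self.right, "right part"))
        if not self.left or not self.right:
            raise ValueError("pattern parts must be non-empty")
        if not (0 <= self.spacer_min <= self.spacer_max):
            raise ValueError("need 0 <= spacer_min <= spacer_max")

    @classmethod
    def from_string(cls, text: str) -> "MotifPattern":
        """Parse e.g. 'CTGN{6,8}WGATAR' or 'CTGN(6-8)WGATAR'."""
        m = re.fullmatch(
            r"([A-Za-z]+)N[\{\(](\d+)[,\-–](\d+)[\}\)]([A-Za-z]+)", text.strip()
        )
        if not m:
            raise ValueError(f"cannot parse motif pattern {text!r}")
        return cls(m.group(1), int(m.group(2)), int(m.group(3)), m.group(4))

    def __str__(self) -> str:
        return f"{self.left}N{{{self.spacer_min},{self.spacer_max}}}{self.right}"

    def expansions(self) -> list[tuple[int, str]]:
        """(spacer_length, concrete IUPAC string) per allowed spacer."""
        return [
            (s, self.left + "N" * s + self.right)
            for s in range(self.spacer_min, self.spacer_max + 1)
        ]

    def reverse_complement(self) -> "MotifPattern":
        return MotifPattern(
            reverse_complement(self.right),
            self.spacer_min,
            self.spacer_max,
            reverse_complement(self.left),
        )


COMPOSITE_EBOX_GATA = MotifPattern("CTG", 6, 8, "WGATAR")

DEFAULT_PATTERN = COMPOSITE_EBOX_GATA


@dataclass(frozen=True)
class MotifHit:
    """A motif match in forward coordinates of the scanned sequence."""

    site_id: str
    offset: int
    length: int
    spacer: int
    strand: str


@dataclass(frozen=True)
class SiteSequence:
    """Sequence window centered on a binding site, with masking count."""

    site_id: str
    seq: str
    masked: int
    chrom: str = ""
    start: int = 0

    def __len__(self) -> int:
        return len(self.seq)


def count_masked(seq: str) -> int:
    """Masked bases = lowercase (soft-masked) plus N/n (hard-masked)."""
    return sum(1 for b in seq if b.islower() or b in "Nn")


def fetch_site_sequences(
    sites: Sequence,
    fasta_path,
    width: int = 200,
    pad: bool = True,
) -> list[SiteSequence]:
    """Retrieve `width`-bp sequences centered on each site from a FASTA.

    Sites may be GenomicInterval-like (chrom/center) or (chrom, center)
    pairs. Windows are [center - width//2, center + width//2); parts
    outside the chromosome are N-padded when pad=True, otherwise an error.
    """
    from pyfaidx import Fasta

    fasta = Fasta(str(fasta_path), as_raw=True, rebuild=True)
    out: list[SiteSequence] = []
    for i, site in enumerate(sites):
        if hasattr(site, "chrom"):
            chrom, center = site.chrom, site.center
        else:
            chrom, center = site
        if chrom not in fasta:
            raise KeyError(f"chromosome {chrom!r} not in FASTA")
        L = len(fasta[chrom])
        lo = center - width // 2
        hi = lo + width
        s, e = max(0, lo), min(L, hi)
        if (s != lo or e != hi) and not pad:
            raise ValueError(f"site {i} window [{lo},{hi}) outside {chrom}")
        seq = str(fasta[chrom][s:e])
        seq = "N" * (s - lo) + seq + "N" * (hi - e)
        out.append(
            SiteSequence(
                site_id=f"site_{i + 1}", seq=seq, masked=count_masked(seq),
                chrom=chrom, start=lo,
            )
        )
    return out


def filter_repeat_masked(
    seqs: Iterable[SiteSequence], max_masked: int = 150
) -> list[SiteSequence]:
    """Drop sites with >= max_masked repeat-masked bases (inclusive bound)."""
    return [s for s in seqs if s.masked < max_masked]


def sample_sites(sites: Sequence, n: int, seed: int) -> list:
    """Uniform subsample without replacement, deterministic per seed."""
    if n > len(sites):
        raise ValueError(f"cannot sample {n} from {len(sites)} sites")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(sites), size=n, replace=False)
    return [sites[int(i)] for i in sorted(idx)]


def _match_table(seq: str) -> dict[str, np.ndarray]:
    """Per-IUPAC-code boolean array over the (uppercased) sequence."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype="S1")
    return {code: np.isin(arr, [b.encode() for b in allowed])
            for code, allowed in IUPAC.items()}


def _scan_concrete(table: dict[str, np.ndarray], pattern: str, seq_len: int) -> np.ndarray:
    """Offsets where a concrete IUPAC string matches, via shifted ANDs."""
    m = len(pattern)
    n = seq_len - m + 1
    if n <= 0:
        return np.array([], dtype=int)
    ok = np.ones(n, dtype=bool)
    for j, code in enumerate(pattern):
        ok &= table[code][j : j + n]
    return np.flatnonzero(ok)


def scan_sequence(
    seq: str | SiteSequence,
    pattern: MotifPattern = DEFAULT_PATTERN,
    both_strands: bool = True,
) -> list[MotifHit]:
    """All (offset, spacer, strand) matches of the composite pattern.

    Matching is case-insensitive; masked lowercase bases are still
    matchable (mask filtering happens upstream). Minus-strand hits are
    matches of the reverse-complemented pattern on the forward sequence,
    reported with their forward-strand offset.
    """
    if isinstance(seq, SiteSequence):
        site_id, text = seq.site_id, seq.seq
    else:
        site_id, text = "seq", seq
    bad = set(text.upper()) - set(IUPAC)
    if bad:
        raise ValueError(f"sequence contains non-IUPAC characters {sorted(bad)}")
    table = _match_table(text)
    hits: list[MotifHit] = []
    patterns = [("+", pattern)]
    if both_strands:
        patterns.append(("-", pattern.reverse_complement()))
    for strand, pat in patterns:
        for spacer, concrete in pat.expansions():
            for off in _scan_concrete(table, concrete, len(text)):
                hits.append(
                    MotifHit(site_id, int(off), len(concrete), spacer, strand)
                )
    hits.sort(key=lambda h: (h.offset, h.spacer, h.strand))
    return hits


def motif_site_proportion(
    seqs: Sequence[SiteSequence | str],
    pattern: MotifPattern = DEFAULT_PATTERN,
    both_strands: bool = True,
    min_sites: int = 0,
) -> tuple[int, int, float]:
    """(n_sites_with_motif, n_sites, fraction); a site counts once.

    min_sites is a reporting threshold: fractions supported by fewer
    motif-containing sites than this are reported as NaN.
    """
    seqs = list(seqs)
    if not seqs:
        raise ValueError("no sequences to scan")
    n_with = sum(
        1 for s in seqs if scan_sequence(s, pattern, both_strands=both_strands)
    )
    fraction = n_with / len(seqs)
    if n_with <= min_sites and min_sites > 0:
        fraction = float("nan")
    return n_with, len(seqs), fraction
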