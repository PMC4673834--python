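"""Nearest-TSS gene assignment and proximal/distal classification.

Each binding site is assigned to the single gene with the nearest
transcription start site on the same chromosome, provided the TSS lies
within 1 Mb of the site center; assignments closer than 5 kb are
`proximal`, the rest `distal`, and sites with no TSS in range are
`unassigned`. The TSS is strand-dependent: interval start for + genes,
end - 1 for - genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genome import FormatError, GenomeIndex, GenomicInterval


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    interval: GenomicInterval

    def __post_init__(self):
        if self.interval.strand not in ("+", "-"):
            raise FormatError(
                f"gene {self.gene_id}: strand must be + or - (TSS undefined otherwise)"
            )

    @property
    def tss(self) -> int:
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class GeneAssignment:
    site_id: str
    gene_id: str | None
    distance: int  # signed: site center - TSS; 0 when the site spans the TSS
    klass: str  # proximal | distal | unassigned


def read_gene_bed(path, genome: GenomeIndex) -> list[GeneModel]:
    """Parse a BED6 gene annotation; genes sorted by (chrom, TSS, id)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: gene BED requires 6 columns")
            try:
                iv = GenomicInterval(
                    fields[0], int(fields[1]), int(fields[2]), fields[5]
                ).check_in(genome)
                genes.append(GeneModel(fields[3], iv))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    genes.sort(key=lambda g: (g.chrom, g.tss, g.gene_id))
    return genes


def assign_nearest_gene(
    sites: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    max_distance: int = 1_000_000,
    proximal_distance: int = 5_000,
) -> list[GeneAssignment]:
    """Single-nearest-TSS assignment within max_distance.

    Ties in |center - TSS| break to the smaller TSS coordinate, then to the
    lexicographically smaller gene id. Distance is 0 when the site interval
    contains the TSS.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for glist in by_chrom.values():
        glist.sort(key=lambda g: (g.tss, g.gene_id))
    tss_arrays = {c: np.array([g.tss for g in glist]) for c, glist in by_chrom.items()}

    out: list[GeneAssignment] = []
    for i, site in enumerate(sites):
        site_id = f"site_{i + 1}"
        glist = by_chrom.get(site.chrom)
        if not glist:
            out.append(GeneAssignment(site_id, None, 0, "unassigned"))
            continue
        center = site.center
        tss = tss_arrays[site.chrom]
        pos = int(np.searchsorted(tss, center))
        # candidate indices around the insertion point; duplicates of the
        # nearest TSS value resolve to the first (lex-smallest id) entry
        cand: list[int] = []
        if pos < len(tss):
            cand.append(pos)
        if pos > 0:
            cand.append(pos - 1)
        best = None
        for j in cand:
            d = abs(center - int(tss[j]))
            key = (d, int(tss[j]), glist[j].gene_id)
            if best is None or key < best[0]:
                best = (key, j)
        # there may be several genes sharing the chosen TSS; pick lex-min id
        (d, chosen_tss, _), j = best
        k = int(np.searchsorted(tss, chosen_tss, side="left"))
        gene = glist[k]
        if d > max_distance:
            out.append(GeneAssignment(site_id, None, 0, "unassigned"))
            continue
        if site.start <= gene.tss < site.end:
            signed = 0
        else:
            signed = center - gene.tss
        klass = "proximal" if abs(signed) < proximal_distance else "distal"
        out.append(GeneAssignment(site_id, gene.gene_id, signed, klass))
    return out


def tss_distance_summary(assignments: Sequence[GeneAssignment]) -> dict[str, float]:
    """Fractions of proximal / distal / unassigned sites (sum exactly 1)."""
    if not assignments:
        raise ValueError("no assignments to summarize")
    n = len(assignments)
    counts = {"proximal": 0, "distal": 0, "unassigned": 0}
    for a in assignments:
        counts[a.klass] += 1
    return {k: v / n for k, v in counts.items()}
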