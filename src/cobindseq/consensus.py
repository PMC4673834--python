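"""Consensus binding regions and negative-binomial significance vs IgG.

Binding sites for one factor are the maximal genomic runs supported by at
least ``min_support`` independent peak callers and at least ``min_length``
bp long. Each region is then scored against an immunoglobulin (IgG)
control with an upper-tail negative-binomial (NB) test: the expected read
count is the control count rescaled to the sample's background level
(floored at the genome-wide background rate for the region's width), and
the NB dispersion is estimated genome-wide from background bins by the
method of moments. Dispersion 0 is the Poisson limit. P-values are
Benjamini-Hochberg adjusted across all candidate regions of the factor,
and sites are kept when read_count >= 10, fold change vs scaled control
>= 2 and adjusted p <= 0.01 (the defaults).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .genome import (
    BinaryTrack,
    CoverageTrack,
    GenomeIndex,
    GenomicInterval,
    ReadIndex,
)


class ModelError(RuntimeError):
    """Background model cannot be fitted or has not been fitted."""


@dataclass(frozen=True)
class NBBackground:
    """Genome-wide negative-binomial background for read counts per bin.

    mean       expected background reads per bin (of the ChIP sample)
    dispersion NB overdispersion alpha, var = mean + alpha * mean^2;
               alpha = 0 is the Poisson limit
    scale      control-to-sample scaling: sample ~ scale * control in
               background territory
    bin_size   bp per bin used during fitting
    """

    bin_size: int
    mean: float
    dispersion: float
    scale: float

    def __post_init__(self):
        if self.mean <= 0:
            raise ModelError(f"background mean must be positive, got {self.mean}")
        if self.dispersion < 0:
            raise ModelError(f"dispersion must be >= 0, got {self.dispersion}")


@dataclass
class ConsensusRegion:
    """A candidate consensus region with its evidence against the control."""

    interval: GenomicInterval
    support: int
    read_count: int = 0
    control_count: int = 0
    fold_change: float = float("nan")
    p_value: float = float("nan")
    q_value: float = float("nan")


@dataclass
class BindingSiteSet:
    """Filtered consensus binding regions for one factor."""

    factor: str
    regions: list[ConsensusRegion]
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.regions)

    def intervals(self) -> list[GenomicInterval]:
        return [r.interval for r in self.regions]

    def centers(self) -> list[tuple[str, int]]:
        return [(r.interval.chrom, r.interval.center) for r in self.regions]

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for i, r in enumerate(self.regions):
            rows.append(
                {
                    "chrom": r.interval.chrom,
                    "start": r.interval.start,
                    "end": r.interval.end,
                    "name": f"{self.factor}_site_{i + 1}",
                    "score": -10.0 * np.log10(max(r.q_value, 1e-300)),
                    "strand": ".",
                    "support": r.support,
                    "read_count": r.read_count,
                    "control_count": r.control_count,
                    "fold_change": r.fold_change,
                    "p_value": r.p_value,
                    "q_value": r.q_value,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "chrom", "start", "end", "name", "score", "strand",
                "support", "read_count", "control_count", "fold_change",
                "p_value", "q_value",
            ],
        )


def sum_binary_tracks(tracks: Sequence[BinaryTrack]) -> CoverageTrack:
    """Per-base sum of caller occupancy tracks (max = number of callers)."""
    if not tracks:
        raise ValueError("need at least one track")
    genome = tracks[0].genome
    for t in tracks[1:]:
        if t.genome != genome:
            raise ValueError("tracks are on different genomes")
    data = {
        c: np.sum([t[c] for t in tracks], axis=0).astype(np.int32) for c in genome
    }
    return CoverageTrack(genome, data)


def call_consensus_regions(
    summed: CoverageTrack, min_support: int = 2, min_length: int = 150
) -> list[GenomicInterval]:
    """Maximal runs with summed caller support >= min_support and
    length >= min_length, sorted and non-overlapping."""
    regions: list[GenomicInterval] = []
    for chrom in summed.genome:
        mask = summed[chrom] >= min_support
        if not mask.any():
            continue
        padded = np.concatenate(([False], mask, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        starts, ends = edges[0::2], edges[1::2]
        for s, e in zip(starts, ends):
            if e - s >= min_length:
                regions.append(GenomicInterval(chrom, int(s), int(e)))
    return regions


def region_support(summed: CoverageTrack, region: GenomicInterval) -> int:
    return int(summed[region.chrom][region.start : region.end].max())


def _bin_counts(
    track: CoverageTrack, bin_size: int, read_length: int
) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """Approximate reads per bin from per-base coverage (full bins only)."""
    counts = []
    keys: list[tuple[str, int]] = []
    for chrom in track.genome:
        n_bins = track.genome[chrom] // bin_size
        if n_bins == 0:
            continue
        v = track[chrom][: n_bins * bin_size].reshape(n_bins, bin_size)
        counts.append(v.sum(axis=1) / read_length)
        keys.extend((chrom, b) for b in range(n_bins))
    if not counts:
        return np.array([]), []
    return np.concatenate(counts), keys


def fit_background_model(
    sample: CoverageTrack,
    control: CoverageTrack,
    exclude: Iterable[GenomicInterval] = (),
    bin_size: int = 1000,
    read_length: int = 200,
    min_bins: int = 30,
) -> NBBackground:
    """Fit the NB background on bins not intersecting candidate regions.

    scale is the least-squares slope through the origin of sample bin
    counts on control bin counts; mean and dispersion come from the
    method of moments on the background sample-bin counts:
    dispersion = max(0, (var - mean) / mean^2).
    """
    if sample.genome != control.genome:
        raise ModelError("sample and control are on different genomes")
    s_counts, keys = _bin_counts(sample, bin_size, read_length)
    c_counts, _ = _bin_counts(control, bin_size, read_length)

    excluded_bins: set[tuple[str, int]] = set()
    for iv in exclude:
        first = iv.start // bin_size
        last = (iv.end - 1) // bin_size
        for b in range(first, last + 1):
            excluded_bins.add((iv.chrom, b))
    keep = np.array([k not in excluded_bins for k in keys], dtype=bool)
    x = c_counts[keep]
    y = s_counts[keep]
    if len(y) < min_bins:
        raise ModelError(
            f"only {len(y)} background bins remain (need >= {min_bins})"
        )
    sxx = float(np.dot(x, x))
    if sxx == 0:
        raise ModelError("control has zero signal in all background bins")
    scale = float(np.dot(x, y)) / sxx
    mean = float(np.mean(y))
    if mean <= 0:
        raise ModelError("sample has zero background signal")
    var = float(np.var(y, ddof=1))
    dispersion = max(0.0, (var - mean) / mean**2)
    return NBBackground(bin_size=bin_size, mean=mean, dispersion=dispersion, scale=scale)


def nb_survival(observed, mean, dispersion: float):
    """Upper-tail P(X >= observed) for NB(mean, dispersion); Poisson at 0."""
    observed = np.asarray(observed)
    if dispersion <= 0:
        return stats.poisson.sf(observed - 1, mean)
    size = 1.0 / dispersion
    p = size / (size + np.asarray(mean, dtype=float))
    return stats.nbinom.sf(observed - 1, size, p)


def score_region(
    region: GenomicInterval,
    sample_reads: ReadIndex,
    control_reads: ReadIndex,
    bg: NBBackground,
    pseudocount: float = 1.0,
) -> tuple[int, int, float, float]:
    """Count reads, compute fold change vs scaled control and NB p-value.

    Returns (read_count, control_count, fold_change, p_value). The
    expected count is max(scale * control_count, bg.mean * len / bin_size)
    so that regions with an empty control are still held to the
    genome-wide background rate.
    """
    read_count = sample_reads.count(region)
    control_count = control_reads.count(region)
    expected = max(
        bg.scale * control_count, bg.mean * len(region) / bg.bin_size
    )
    fold_change = (read_count + pseudocount) / (bg.scale * control_count + pseudocount)
    p_value = float(nb_survival(read_count, expected, bg.dispersion))
    return read_count, control_count, fold_change, p_value


def adjust_pvalues_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def filter_binding_sites(
    scored_regions: Sequence[ConsensusRegion],
    min_reads: int = 10,
    min_fc: float = 2.0,
    max_q: float = 0.01,
    factor: str = "factor",
) -> BindingSiteSet:
    """Keep regions with read_count >= min_reads, FC >= min_fc, q <= max_q."""
    kept = [
        r
        for r in scored_regions
        if r.read_count >= min_reads and r.fold_change >= min_fc and r.q_value <= max_q
    ]
    return BindingSiteSet(
        factor=factor,
        regions=kept,
        params={"min_reads": min_reads, "min_fc": min_fc, "max_q": max_q},
    )


class ConsensusPeakCaller(BaseEstimator):
    """Consensus binding-site detection with NB significance vs a control.

    scikit-learn-style estimator: ``fit`` consumes the per-caller peak
    lists together with the extended sample/control reads and a genome,
    and exposes the fitted background model and the filtered site set as
    trailing-underscore attributes.

    Parameters
    ----------
    min_support : minimum number of agreeing callers per base (>= 2).
    min_length : minimum consensus-region length in bp.
    bin_size : background-model bin width in bp.
    read_length : extended read length used to de-convolve coverage into
        read counts per bin.
    min_reads, min_fc, max_q : site filters (reads >= 10, fold change
        >= 2 vs scaled IgG, BH-adjusted p <= 0.01 by default).
    pseudocount : added to numerator and scaled denominator of the fold
        change.
    factor : name recorded in the output site set.
    """

    def __init__(
        self,
        min_support: int = 2,
        min_length: int = 150,
        bin_size: int = 1000,
        read_length: int = 200,
        min_reads: int = 10,
        min_fc: float = 2.0,
        max_q: float = 0.01,
        pseudocount: float = 1.0,
        factor: str = "factor",
    ):
        self.min_support = min_support
        self.min_length = min_length
        self.bin_size = bin_size
        self.read_length = read_length
        self.min_reads = min_reads
        self.min_fc = min_fc
        self.max_q = max_q
        self.pseudocount = pseudocount
        self.factor = factor

    def fit(
        self,
        caller_peaks: Sequence[Sequence[GenomicInterval]],
        y=None,
        *,
        sample_reads: Sequence[GenomicInterval],
        control_reads: Sequence[GenomicInterval],
        genome: GenomeIndex,
    ):
        from .genome import binarize_occupancy

        if len(caller_peaks) < 2:
            raise ValueError("need peak lists from >= 2 callers")
        tracks = [binarize_occupancy(peaks, genome) for peaks in caller_peaks]
        summed = sum_binary_tracks(tracks)
        regions = call_consensus_regions(summed, self.min_support, self.min_length)

        from .genome import coverage_from_intervals

        sample_cov = coverage_from_intervals(sample_reads, genome)
        control_cov = coverage_from_intervals(control_reads, genome)
        # exclude every caller-reported peak, not just the consensus, so
        # sites missed by the consensus rule cannot contaminate the
        # background moments
        exclude = list(regions)
        for peaks in caller_peaks:
            exclude.extend(peaks)
        self.background_ = fit_background_model(
            sample_cov,
            control_cov,
            exclude=exclude,
            bin_size=self.bin_size,
            read_length=self.read_length,
        )

        s_idx = ReadIndex(sample_reads, genome)
        c_idx = ReadIndex(control_reads, genome)
        candidates: list[ConsensusRegion] = []
        for iv in regions:
            rc, cc, fc, p = score_region(
                iv, s_idx, c_idx, self.background_, self.pseudocount
            )
            candidates.append(
                ConsensusRegion(
                    interval=iv,
                    support=region_support(summed, iv),
                    read_count=rc,
                    control_count=cc,
                    fold_change=fc,
                    p_value=p,
                )
            )
        qs = adjust_pvalues_bh([c.p_value for c in candidates])
        for c, q in zip(candidates, qs):
            c.q_value = float(q)

        self.summed_ = summed
        self.candidates_ = candidates
        self.sites_ = filter_binding_sites(
            candidates, self.min_reads, self.min_fc, self.max_q, self.factor
        )
        self.sites_.params.update(
            min_support=self.min_support,
            min_length=self.min_length,
            pseudocount=self.pseudocount,
            background=dataclasses.asdict(self.background_),
        )
        return self
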