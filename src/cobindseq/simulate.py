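"""Ground-truthed synthetic ChIP-seq inputs for two co-binding factors.

The generator emulates the statistical structure the pipeline assumes:

* a small uniform-random genome with contiguous soft-masked (lowercase)
  repeat stretches;
* planted binding sites for two factors A and B with configurable class
  fractions (shared, A_only, B_only; default 0.6/0.2/0.2, echoing the
  observed predominance of co-occupied sites);
* the composite E-box/GATA motif CTG-N(6-8)-WGATAR written into the
  sequence at A-bound site centers with a configurable probability;
* enriched-sample and IgG coverage: negative-binomial background reads
  per kb plus Poisson(enrichment) site reads whose midpoints are
  Normal(center, 60 bp); all reads are emitted directly as 200-bp
  extended intervals (alignment is out of scope);
* three imperfect peak callers per factor, each reporting a true site
  with probability `caller_sensitivity`, jittering both edges, and adding
  Poisson false-positive peaks;
* a non-overlapping stranded gene annotation.

Every artifact is a pure function of (config, seed): independent random
streams are derived per artifact so regenerating any one of them is
reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome import GenomeIndex, GenomicInterval
from . import io as cio

CLASSES = ("shared", "A_only", "B_only")

# fixed stream ids so each artifact has its own reproducible RNG
_STREAM = {
    "genome": 1,
    "landscape": 2,
    "coverage_A": 3,
    "coverage_B": 4,
    "coverage_IgG": 5,
    "callers_A": 6,
    "callers_B": 7,
    "genes": 8,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAM[stream]])


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Defaults are the conditions the pipeline is exercised under: 1,500
    sites on a 10-Mb genome, 30 expected reads per bound site and factor,
    1 background read per kb with NB dispersion 0.2, class fractions
    0.6/0.2/0.2 and three callers at 0.9 sensitivity.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 5_000_000
    n_sites: int = 1500
    class_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    enrichment: float = 30.0            # expected reads per bound site per factor
    background_rate: float = 1.0        # background reads per kb
    nb_dispersion: float = 0.2
    motif_prob: dict = field(
        default_factory=lambda: {"shared": 0.9, "A_only": 0.9, "B_only": 0.0}
    )
    repeat_fraction: float = 0.1
    caller_sensitivity: float = 0.9
    caller_fp_rate: float = 5.0         # spurious peaks per Mb per caller
    caller_jitter_sd: float = 30.0      # bp, per peak edge
    n_callers: int = 3
    n_genes: int = 200
    read_length: int = 200
    site_read_sd: float = 60.0          # SD of read midpoints around the center
    min_spacing: int = 2000             # minimum distance between site centers
    peak_halfwidth: int = 300           # caller-reported half-width
    gene_min_length: int = 2000
    gene_max_length: int = 10000

    def __post_init__(self):
        f = self.class_fractions
        if any(x < 0 for x in f) or abs(sum(f) - 1.0) > 1e-9:
            raise ValueError("class fractions must be >= 0 and sum to 1")
        for name in ("enrichment", "background_rate", "nb_dispersion",
                     "repeat_fraction", "caller_fp_rate", "caller_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name, p in [("caller_sensitivity", self.caller_sensitivity),
                        *[(f"motif_prob[{k}]", v) for k, v in self.motif_prob.items()]]:
            if not (0 <= p <= 1):
                raise ValueError(f"{name} must be a probability")

    @property
    def genome_size(self) -> int:
        return self.n_chromosomes * self.chrom_length


@dataclass(frozen=True)
class PlantedSite:
    chrom: str
    center: int
    klass: str                      # shared | A_only | B_only
    motif_start: int = -1           # genome coordinate; -1 = no motif embedded
    motif_spacer: int = -1

    def bound_by(self, factor: str) -> bool:
        return self.klass == "shared" or self.klass == f"{factor}_only"


@dataclass
class SyntheticTruth:
    sites: list[PlantedSite]
    caller_false_positives: dict[str, list[GenomicInterval]] = field(
        default_factory=dict
    )  # key "A_1" = factor A, caller 1

    def sites_bound_by(self, factor: str) -> list[PlantedSite]:
        return [s for s in self.sites if s.bound_by(factor)]


def simulate_genome(
    config: SimulationConfig,
) -> tuple[GenomeIndex, dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Random A/C/G/T genome with contiguous soft-masked stretches.

    Returns (index, sequences, mask) where sequences are uint8 arrays of
    uppercase base codes and mask is a boolean repeat indicator; the
    FASTA writer lowercases masked bases.
    """
    rng = _rng(config.seed, "genome")
    genome = GenomeIndex(
        (f"chr{i + 1}", config.chrom_length) for i in range(config.n_chromosomes)
    )
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    for chrom in genome:
        L = genome[chrom]
        seqs[chrom] = bases[rng.integers(0, 4, size=L)]
        mask = np.zeros(L, dtype=bool)
        target = int(config.repeat_fraction * L)
        while mask.sum() < target:
            length = max(100, int(rng.exponential(500)))
            start = int(rng.integers(0, max(1, L - length)))
            mask[start : start + length] = True
        masks[chrom] = mask
    return genome, seqs, masks


def render_fasta(
    seqs: dict[str, np.ndarray], masks: dict[str, np.ndarray]
) -> dict[str, str]:
    """Apply soft-masking (lowercase) and return text sequences."""
    out = {}
    for chrom, arr in seqs.items():
        s = arr.copy()
        m = masks[chrom]
        s[m] = s[m] + 32  # ASCII uppercase -> lowercase
        out[chrom] = s.tobytes().decode("ascii")
    return out


def simulate_binding_landscape(
    config: SimulationConfig,
    genome: GenomeIndex,
    seqs: dict[str, np.ndarray] | None = None,
) -> SyntheticTruth:
    """Plant site centers (uniform, min spacing 2 kb), classes and motifs.

    When `seqs` is given, the composite motif is written into the sequence
    at A-bound sites (classes shared/A_only) with the configured
    probability; B_only sites never receive the motif by default.
    """
    rng = _rng(config.seed, "landscape")
    margin = 1000
    # allocate sites to chromosomes proportionally to length
    lengths = np.array([genome[c] for c in genome], dtype=float)
    counts = rng.multinomial(config.n_sites, lengths / lengths.sum())
    sites: list[PlantedSite] = []
    for chrom, n in zip(genome, counts):
        n = int(n)
        if n == 0:
            continue
        L = genome[chrom]
        span = L - 2 * margin - (n - 1) * config.min_spacing
        if span <= 0:
            raise ValueError(
                f"genome too small: {n} sites at {config.min_spacing} bp "
                f"spacing do not fit on {chrom} ({L} bp)"
            )
        u = np.sort(rng.uniform(0, span, size=n))
        centers = (margin + u + config.min_spacing * np.arange(n)).astype(int)
        classes = rng.choice(CLASSES, size=n, p=config.class_fractions)
        for center, klass in zip(centers, classes):
            motif_start, spacer = -1, -1
            if seqs is not None and rng.random() < config.motif_prob.get(klass, 0.0):
                spacer = int(rng.integers(6, 9))
                w = "AT"[rng.integers(0, 2)]
                r = "AG"[rng.integers(0, 2)]
                spacer_seq = "".join(
                    "ACGT"[i] for i in rng.integers(0, 4, size=spacer)
                )
                motif = f"CTG{spacer_seq}{w}GATA{r}"
                motif_start = int(center) - len(motif) // 2
                arr = np.frombuffer(motif.encode("ascii"), dtype=np.uint8)
                seqs[chrom][motif_start : motif_start + len(motif)] = arr
            sites.append(
                PlantedSite(chrom, int(center), str(klass), motif_start, spacer)
            )
    return SyntheticTruth(sites=sites)


def _nb_counts(rng, mean: float, dispersion: float, size: int) -> np.ndarray:
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


def simulate_coverage(
    truth: SyntheticTruth,
    config: SimulationConfig,
    genome: GenomeIndex,
    factor: str,
) -> list[GenomicInterval]:
    """Extended-read intervals for factor 'A', 'B' or 'IgG'.

    Background reads per kb ~ NB(background_rate, dispersion) with uniform
    positions; bound sites add Poisson(enrichment) reads with midpoints
    Normal(center, site_read_sd), truncated to the chromosome. IgG gets
    background only.
    """
    if factor not in ("A", "B", "IgG"):
        raise ValueError(f"unknown factor {factor!r}")
    rng = _rng(config.seed, f"coverage_{factor}")
    rl = config.read_length
    reads: list[GenomicInterval] = []
    for chrom in genome:
        L = genome[chrom]
        n_kb = L // 1000
        counts = _nb_counts(rng, config.background_rate, config.nb_dispersion, n_kb)
        total = int(counts.sum())
        offsets = rng.uniform(0, 1000, size=total)
        kb_index = np.repeat(np.arange(n_kb), counts)
        starts = (kb_index * 1000 + offsets).astype(int)
        starts = np.clip(starts, 0, L - 1)
        for s in starts:
            reads.append(GenomicInterval(chrom, int(s), min(int(s) + rl, L)))
    if factor != "IgG":
        for site in truth.sites_bound_by(factor):
            n = int(rng.poisson(config.enrichment))
            if n == 0:
                continue
            L = genome[site.chrom]
            mids = rng.normal(site.center, config.site_read_sd, size=n)
            starts = np.clip((mids - rl / 2).astype(int), 0, L - 1)
            for s in starts:
                reads.append(GenomicInterval(site.chrom, int(s), min(int(s) + rl, L)))
    return reads


def simulate_caller_outputs(
    truth: SyntheticTruth,
    config: SimulationConfig,
    genome: GenomeIndex,
    factor: str,
    n_callers: int | None = None,
) -> list[list[GenomicInterval]]:
    """Imperfect peak calls per caller; false positives recorded in truth."""
    if factor not in ("A", "B"):
        raise ValueError(f"unknown factor {factor!r}")
    rng = _rng(config.seed, f"callers_{factor}")
    n_callers = n_callers if n_callers is not None else config.n_callers
    hw = config.peak_halfwidth
    bound = truth.sites_bound_by(factor)
    outputs: list[list[GenomicInterval]] = []
    lengths = np.array([genome[c] for c in genome], dtype=float)
    names = list(genome)
    for ci in range(n_callers):
        peaks: list[GenomicInterval] = []
        for site in bound:
            if rng.random() >= config.caller_sensitivity:
                continue
            L = genome[site.chrom]
            s = site.center - hw + rng.normal(0, config.caller_jitter_sd)
            e = site.center + hw + rng.normal(0, config.caller_jitter_sd)
            s = int(max(0, min(s, L - 2)))
            e = int(min(L, max(e, s + 1)))
            peaks.append(GenomicInterval(site.chrom, s, e))
        n_fp = int(rng.poisson(config.caller_fp_rate * genome.total_size / 1e6))
        fps: list[GenomicInterval] = []
        for _ in range(n_fp):
            chrom = names[int(rng.choice(len(names), p=lengths / lengths.sum()))]
            L = genome[chrom]
            center = int(rng.integers(hw, L - hw))
            fp = GenomicInterval(chrom, center - hw, center + hw)
            peaks.append(fp)
            fps.append(fp)
        truth.caller_false_positives[f"{factor}_{ci + 1}"] = fps
        peaks.sort()
        outputs.append(peaks)
    return outputs


def simulate_gene_annotation(
    config: SimulationConfig, genome: GenomeIndex
) -> list:
    """Non-overlapping stranded genes, uniformly placed."""
    from .annotate import GeneModel

    rng = _rng(config.seed, "genes")
    lengths_by_chrom = np.array([genome[c] for c in genome], dtype=float)
    counts = rng.multinomial(config.n_genes, lengths_by_chrom / lengths_by_chrom.sum())
    genes: list[GeneModel] = []
    gid = 0
    for chrom, n in zip(genome, counts):
        n = int(n)
        if n == 0:
            continue
        L = genome[chrom]
        glens = rng.integers(config.gene_min_length, config.gene_max_length + 1, size=n)
        free = L - int(glens.sum())
        if free <= 0:
            raise ValueError(f"genome too small for {n} genes on {chrom}")
        gaps = np.sort(rng.uniform(0, free, size=n)).astype(int)
        starts = gaps + np.concatenate(([0], np.cumsum(glens)[:-1]))
        strands = rng.choice(["+", "-"], size=n)
        for s, gl, st in zip(starts, glens, strands):
            gid += 1
            genes.append(
                GeneModel(
                    f"gene_{gid:04d}",
                    GenomicInterval(chrom, int(s), int(s + gl), str(st)),
                )
            )
    return genes


def write_truth(truth: SyntheticTruth, sites_path, fp_path) -> None:
    with open(sites_path, "w") as fh:
        fh.write("chrom\tcenter\tclass\tmotif_start\tmotif_spacer\n")
        for s in truth.sites:
            fh.write(
                f"{s.chrom}\t{s.center}\t{s.klass}\t{s.motif_start}\t{s.motif_spacer}\n"
            )
    with open(fp_path, "w") as fh:
        fh.write("caller\tchrom\tstart\tend\n")
        for key, fps in sorted(truth.caller_false_positives.items()):
            for iv in fps:
                fh.write(f"{key}\t{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_truth(sites_path, fp_path=None) -> SyntheticTruth:
    sites: list[PlantedSite] = []
    with open(sites_path) as fh:
        header = fh.readline()
        for line in fh:
            chrom, center, klass, mstart, mspacer = line.rstrip("\n").split("\t")
            sites.append(
                PlantedSite(chrom, int(center), klass, int(mstart), int(mspacer))
            )
    truth = SyntheticTruth(sites=sites)
    if fp_path is not None:
        with open(fp_path) as fh:
            fh.readline()
            for line in fh:
                key, chrom, start, end = line.rstrip("\n").split("\t")
                truth.caller_false_positives.setdefault(key, []).append(
                    GenomicInterval(chrom, int(start), int(end))
                )
    return truth


@dataclass
class SimulatedDataset:
    """In-memory bundle of everything one simulation produced."""

    config: SimulationConfig
    genome: GenomeIndex
    sequences: dict[str, np.ndarray]
    masks: dict[str, np.ndarray]
    truth: SyntheticTruth
    reads: dict[str, list[GenomicInterval]]       # A, B, IgG
    caller_peaks: dict[str, list[list[GenomicInterval]]]  # A, B
    genes: list


def simulate_all(config: SimulationConfig, with_sequence: bool = True) -> SimulatedDataset:
    """Generate the full dataset in memory (pure function of the config)."""
    if with_sequence:
        genome, seqs, masks = simulate_genome(config)
    else:
        genome = GenomeIndex(
            (f"chr{i + 1}", config.chrom_length)
            for i in range(config.n_chromosomes)
        )
        seqs, masks = {}, {}
    truth = simulate_binding_landscape(config, genome, seqs if with_sequence else None)
    reads = {f: simulate_coverage(truth, config, genome, f) for f in ("A", "B", "IgG")}
    callers = {
        f: simulate_caller_outputs(truth, config, genome, f) for f in ("A", "B")
    }
    genes = simulate_gene_annotation(config, genome)
    return SimulatedDataset(config, genome, seqs, masks, truth, reads, callers, genes)


def simulate_dataset(config: SimulationConfig, outdir) -> dict[str, Path]:
    """Generate and write the complete dataset; returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = simulate_all(config)
    paths: dict[str, Path] = {}

    paths["chrom_sizes"] = outdir / "genome.chrom.sizes"
    with open(paths["chrom_sizes"], "w") as fh:
        for chrom in ds.genome:
            fh.write(f"{chrom}\t{ds.genome[chrom]}\n")

    paths["fasta"] = outdir / "genome.fa"
    cio.write_fasta(render_fasta(ds.sequences, ds.masks), paths["fasta"])

    for factor in ("A", "B", "IgG"):
        key = f"reads_{factor}"
        paths[key] = outdir / f"reads_{factor}.bed"
        cio.write_bed(ds.reads[factor], paths[key])
    for factor in ("A", "B"):
        for ci, peaks in enumerate(ds.caller_peaks[factor]):
            key = f"caller_{factor}_{ci + 1}"
            paths[key] = outdir / f"caller_{factor}_{ci + 1}.bed"
            cio.write_bed(peaks, paths[key])

    paths["genes"] = outdir / "genes.bed"
    with open(paths["genes"], "w") as fh:
        for g in ds.genes:
            iv = g.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.gene_id}\t0\t{iv.strand}\n")

    paths["truth_sites"] = outdir / "truth_sites.tsv"
    paths["truth_caller_fp"] = outdir / "truth_caller_fp.tsv"
    write_truth(ds.truth, paths["truth_sites"], paths["truth_caller_fp"])

    paths["config"] = outdir / "sim_config.txt"
    with open(paths["config"], "w") as fh:
        for f_ in dataclasses.fields(config):
            fh.write(f"{f_.name} = {getattr(config, f_.name)}\n")
    return paths
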