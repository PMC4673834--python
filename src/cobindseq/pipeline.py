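"""End-to-end pipeline: simulate/load -> consensus -> co-binding -> motif
-> TSS annotation, with a flat config file, structured logging and a
deterministic run manifest.

The manifest records the resolved config, per-stage output checksums and
record counts; re-running with an identical config yields byte-identical
outputs and therefore an identical manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as cio
from .annotate import assign_nearest_gene, read_gene_bed, tss_distance_summary
from .cobinding import (
    CoBindingClassifier,
    merge_factor_sites,
    profile_matrix,
    subtract_control,
)
from .consensus import ConsensusPeakCaller
from .genome import GenomicInterval, coverage_from_intervals
from .motif import (
    MotifPattern,
    fetch_site_sequences,
    filter_repeat_masked,
    motif_site_proportion,
)
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger("cobindseq.pipeline")


class ConfigError(ValueError):
    """Invalid pipeline configuration (raised before any stage runs)."""


@dataclass
class PipelineConfig:
    """All stage parameters plus either input paths or a simulate block."""

    seed: int = 0
    simulate: bool = True

    # input paths (ignored when simulate=True; filled in from the simulator)
    chrom_sizes: str = ""
    fasta: str = ""
    reads_a: str = ""
    reads_b: str = ""
    reads_igg: str = ""
    callers_a: str = ""   # comma-separated BED paths
    callers_b: str = ""
    genes: str = ""
    factor_a: str = "A"
    factor_b: str = "B"

    # consensus / scoring
    extension: int = 200
    min_support: int = 2
    min_length: int = 150
    bin_size: int = 1000
    min_reads: int = 10
    min_fc: float = 2.0
    max_q: float = 0.01
    pseudocount: float = 1.0

    # co-binding
    pairing_distance: int = 250
    half_window: int = 500
    subwindow: int = 25
    k: int = 3
    zscore_mode: str = "column"
    n_init: int = 10

    # motif
    motif: str = "CTGN{6,8}WGATAR"
    seq_width: int = 200
    max_masked: int = 150

    # annotation
    max_gene_distance: int = 1_000_000
    proximal_distance: int = 5_000

    # simulate block
    sim_n_chromosomes: int = 2
    sim_chrom_length: int = 5_000_000
    sim_n_sites: int = 1500
    sim_fraction_shared: float = 0.6
    sim_fraction_a_only: float = 0.2
    sim_fraction_b_only: float = 0.2
    sim_enrichment: float = 30.0
    sim_background_rate: float = 1.0
    sim_nb_dispersion: float = 0.2
    sim_repeat_fraction: float = 0.1
    sim_caller_sensitivity: float = 0.9
    sim_caller_fp_rate: float = 5.0
    sim_caller_jitter_sd: float = 30.0
    sim_n_genes: int = 200

    def validate(self) -> None:
        positive = [
            "extension", "min_support", "min_length", "bin_size", "min_reads",
            "pairing_distance", "half_window", "subwindow", "k",
            "seq_width", "max_masked", "max_gene_distance", "proximal_distance",
            "n_init",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"parameter {name} must be positive")
        if self.min_fc < 0 or not (0 < self.max_q <= 1):
            raise ConfigError("min_fc must be >= 0 and 0 < max_q <= 1")
        if self.half_window % self.subwindow != 0:
            raise ConfigError("half_window must be divisible by subwindow")
        if self.zscore_mode not in ("site", "column"):
            raise ConfigError("zscore_mode must be 'site' or 'column'")
        MotifPattern.from_string(self.motif)  # raises on a malformed pattern
        if not self.simulate:
            needed = ["chrom_sizes", "fasta", "reads_a", "reads_b", "reads_igg",
                      "callers_a", "callers_b", "genes"]
            for name in needed:
                if not getattr(self, name):
                    raise ConfigError(f"simulate=false requires input path {name}")
                # caller lists are comma-separated
            for name in needed:
                for p in str(getattr(self, name)).split(","):
                    if not Path(p).exists():
                        raise ConfigError(f"input file not found: {p}")

    def sim_config(self) -> SimulationConfig:
        return SimulationConfig(
            seed=self.seed,
            n_chromosomes=self.sim_n_chromosomes,
            chrom_length=self.sim_chrom_length,
            n_sites=self.sim_n_sites,
            class_fractions=(
                self.sim_fraction_shared,
                self.sim_fraction_a_only,
                self.sim_fraction_b_only,
            ),
            enrichment=self.sim_enrichment,
            background_rate=self.sim_background_rate,
            nb_dispersion=self.sim_nb_dispersion,
            repeat_fraction=self.sim_repeat_fraction,
            caller_sensitivity=self.sim_caller_sensitivity,
            caller_fp_rate=self.sim_caller_fp_rate,
            caller_jitter_sd=self.sim_caller_jitter_sd,
            n_genes=self.sim_n_genes,
            read_length=self.extension,
        )


_BOOL = {"true": True, "false": False, "1": True, "0": False,
         "yes": True, "no": False}


def read_config(path) -> PipelineConfig:
    """Parse a flat `key = value` config file."""
    values: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            values[key.strip()] = value.strip()
    fields = {f.name: f for f in dataclasses.fields(PipelineConfig)}
    kwargs = {}
    for key, raw in values.items():
        if key not in fields:
            raise ConfigError(f"unknown config key {key!r}")
        ftype = fields[key].type
        if ftype == "bool":
            if raw.lower() not in _BOOL:
                raise ConfigError(f"config key {key}: not a boolean: {raw!r}")
            kwargs[key] = _BOOL[raw.lower()]
        elif ftype == "int":
            kwargs[key] = int(raw)
        elif ftype == "float":
            kwargs[key] = float(raw)
        else:
            kwargs[key] = raw
    return PipelineConfig(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig, outdir, seed: int | None = None) -> Path:
    """Execute all stages; returns the path of the written manifest."""
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("cobindseq")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
    }

    def record(stage: str, outputs: dict[str, Path], counts: dict[str, int]) -> None:
        manifest["stages"][stage] = {
            "outputs": {p.name: _sha256(p) for p in outputs.values()},
            "counts": counts,
        }
        logger.info("stage %s: %s", stage, counts)

    try:
        # ---- stage: simulate or load -----------------------------------
        if config.simulate:
            sim_dir = outdir / "sim"
            paths = simulate_dataset(config.sim_config(), sim_dir)
            record(
                "simulate",
                paths,
                {"n_sites": config.sim_n_sites, "n_genes": config.sim_n_genes},
            )
            chrom_sizes, fasta = paths["chrom_sizes"], paths["fasta"]
            reads_paths = {f: paths[f"reads_{f}"] for f in ("A", "B", "IgG")}
            caller_paths = {
                "A": [paths[f"caller_A_{i + 1}"] for i in range(3)],
                "B": [paths[f"caller_B_{i + 1}"] for i in range(3)],
            }
            genes_path = paths["genes"]
        else:
            chrom_sizes, fasta = Path(config.chrom_sizes), Path(config.fasta)
            reads_paths = {
                "A": Path(config.reads_a),
                "B": Path(config.reads_b),
                "IgG": Path(config.reads_igg),
            }
            caller_paths = {
                "A": [Path(p) for p in config.callers_a.split(",")],
                "B": [Path(p) for p in config.callers_b.split(",")],
            }
            genes_path = Path(config.genes)

        genome = cio.read_chrom_sizes(chrom_sizes)
        reads = {k: cio.read_bed(p, genome) for k, p in reads_paths.items()}
        callers = {
            k: [cio.read_bed(p, genome) for p in plist]
            for k, plist in caller_paths.items()
        }

        # ---- stage: consensus per factor -------------------------------
        site_sets = {}
        scorers = {}
        factor_names = {"A": config.factor_a, "B": config.factor_b}
        cons_outputs = {}
        cons_counts = {}
        for key in ("A", "B"):
            caller = ConsensusPeakCaller(
                min_support=config.min_support,
                min_length=config.min_length,
                bin_size=config.bin_size,
                read_length=config.extension,
                min_reads=config.min_reads,
                min_fc=config.min_fc,
                max_q=config.max_q,
                pseudocount=config.pseudocount,
                factor=factor_names[key],
            ).fit(
                callers[key],
                sample_reads=reads[key],
                control_reads=reads["IgG"],
                genome=genome,
            )
            scorers[key] = caller
            site_sets[key] = caller.sites_
            path = outdir / f"sites_{factor_names[key]}.tsv"
            _write_tsv(caller.sites_.to_dataframe(), path)
            cons_outputs[f"sites_{key}"] = path
            cons_counts[f"{key}_candidates"] = len(caller.candidates_)
            cons_counts[f"{key}_passing"] = len(caller.sites_)
        record("consensus", cons_outputs, cons_counts)

        # ---- stage: co-binding ------------------------------------------
        combined = merge_factor_sites(
            site_sets["A"], site_sets["B"], config.pairing_distance
        )
        cov = {k: coverage_from_intervals(reads[k], genome) for k in ("A", "B", "IgG")}
        subtracted = {
            k: subtract_control(cov[k], cov["IgG"], scorers[k].background_)
            for k in ("A", "B")
        }
        profiles = profile_matrix(
            combined, subtracted["A"], subtracted["B"],
            config.half_window, config.subwindow,
        )
        clf = CoBindingClassifier(
            n_clusters=config.k,
            n_init=config.n_init,
            random_state=config.seed,
            zscore_mode=config.zscore_mode,
        ).fit(profiles)

        w = 2 * config.half_window // config.subwindow
        col_names = [f"track{t}_w{j + 1:02d}" for t in ("A", "B") for j in range(w)]
        site_ids = [f"combined_{i + 1}" for i in range(len(combined))]
        combined_df = pd.DataFrame(
            {
                "site_id": site_ids,
                "chrom": [s.chrom for s in combined],
                "center": [s.center for s in combined],
                "source": [s.source for s in combined],
                "cluster": clf.labels_,
                "class": clf.site_classes_ if config.k == 3 else clf.labels_,
            }
        )
        cobind_outputs = {}
        p = outdir / "combined_sites.tsv"
        _write_tsv(combined_df, p)
        cobind_outputs["combined_sites"] = p
        p = outdir / "profile_matrix.tsv"
        _write_tsv(
            pd.DataFrame(profiles, columns=col_names).assign(site_id=site_ids)[
                ["site_id"] + col_names
            ],
            p,
        )
        cobind_outputs["profile_matrix"] = p
        p = outdir / "zscore_matrix.tsv"
        _write_tsv(
            pd.DataFrame(clf.zmatrix_, columns=col_names).assign(site_id=site_ids)[
                ["site_id"] + col_names
            ],
            p,
        )
        cobind_outputs["zscore_matrix"] = p
        class_counts = combined_df["class"].value_counts().to_dict()
        record(
            "cobinding",
            cobind_outputs,
            {"n_combined": len(combined), **{str(k): int(v) for k, v in class_counts.items()}},
        )

        # ---- stage: motif -----------------------------------------------
        pattern = MotifPattern.from_string(config.motif)
        seqs = fetch_site_sequences(combined, fasta, width=config.seq_width)
        rows = []
        for klass in ("shared", "A_only", "B_only"):
            klass_seqs = [
                s for s, c in zip(seqs, clf.site_classes_) if c == klass
            ] if config.k == 3 else []
            klass_seqs = filter_repeat_masked(klass_seqs, config.max_masked)
            if klass_seqs:
                n_with, n_total, frac = motif_site_proportion(klass_seqs, pattern)
            else:
                n_with, n_total, frac = 0, 0, float("nan")
            rows.append(
                {"class": klass, "n_total": n_total, "n_with_motif": n_with,
                 "fraction": frac}
            )
        motif_df = pd.DataFrame(rows)
        p = outdir / "motif_summary.tsv"
        _write_tsv(motif_df, p)
        record("motif", {"motif_summary": p}, {"n_sequences": len(seqs)})

        # ---- stage: annotation ------------------------------------------
        gene_models = read_gene_bed(genes_path, genome)
        site_intervals = [
            GenomicInterval(s.chrom, max(0, s.center - 1), s.center + 1)
            for s in combined
        ]
        assignments = assign_nearest_gene(
            site_intervals, gene_models,
            max_distance=config.max_gene_distance,
            proximal_distance=config.proximal_distance,
        )
        assign_df = pd.DataFrame(
            {
                "site_id": site_ids,
                "gene": [a.gene_id or "." for a in assignments],
                "distance": [a.distance for a in assignments],
                "class": [a.klass for a in assignments],
            }
        )
        ann_outputs = {}
        p = outdir / "gene_assignments.tsv"
        _write_tsv(assign_df, p)
        ann_outputs["gene_assignments"] = p
        summary = tss_distance_summary(assignments)
        p = outdir / "tss_summary.tsv"
        _write_tsv(
            pd.DataFrame([summary])[["proximal", "distal", "unassigned"]], p
        )
        ann_outputs["tss_summary"] = p
        for klass in ("proximal", "distal"):
            gene_list = sorted(
                {a.gene_id for a in assignments if a.klass == klass and a.gene_id}
            )
            p = outdir / f"genes_{klass}.txt"
            p.write_text("".join(g + "\n" for g in gene_list))
            ann_outputs[f"genes_{klass}"] = p
        record(
            "annotation",
            ann_outputs,
            {k: int(v * len(assignments)) for k, v in summary.items()},
        )

        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, sort_keys=True, indent=2) + "\n")
        return manifest_path
    finally:
        root.removeHandler(handler)
        handler.close()
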