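"""Determinism, moment and geometry checks on the synthetic-data generator."""

import collections

import numpy as np
import pytest
from scipy import stats

from cobindseq.genome import coverage_from_intervals
from cobindseq.motif import scan_sequence
from cobindseq.simulate import (
    SimulationConfig,
    read_truth,
    render_fasta,
    simulate_all,
    simulate_binding_landscape,
    simulate_caller_outputs,
    simulate_coverage,
    simulate_dataset,
    simulate_gene_annotation,
    simulate_genome,
    write_truth,
)


def small_config(**kw):
    defaults = dict(
        seed=11, n_chromosomes=1, chrom_length=300_000, n_sites=60, n_genes=20
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestGenome:
    def test_mask_fraction_in_range(self):
        config = small_config(chrom_length=100_000, repeat_fraction=0.1)
        _, _, masks = simulate_genome(config)
        frac = masks["chr1"].mean()
        assert 0.08 <= frac <= 0.12

    def test_deterministic_fasta(self, tmp_path):
        config = small_config(chrom_length=100_000, n_sites=20, n_genes=5)
        for d in ("a", "b"):
            simulate_dataset(config, tmp_path / d)
        assert (tmp_path / "a/genome.fa").read_bytes() == (
            tmp_path / "b/genome.fa"
        ).read_bytes()

    def test_zero_mask_fraction_no_lowercase(self):
        config = small_config(chrom_length=50_000, repeat_fraction=0.0)
        genome, seqs, masks = simulate_genome(config)
        text = render_fasta(seqs, masks)["chr1"]
        assert text == text.upper()


class TestLandscape:
    def test_all_shared_when_fraction_one(self):
        config = small_config(class_fractions=(1.0, 0.0, 0.0))
        genome, seqs, masks = simulate_genome(config)
        truth = simulate_binding_landscape(config, genome, seqs)
        assert all(s.klass == "shared" for s in truth.sites)

    def test_embedded_motif_always_scannable(self):
        config = small_config(
            class_fractions=(1.0, 0.0, 0.0),
            motif_prob={"shared": 1.0, "A_only": 1.0, "B_only": 0.0},
        )
        genome, seqs, masks = simulate_genome(config)
        truth = simulate_binding_landscape(config, genome, seqs)
        text = render_fasta(seqs, masks)["chr1"]
        for site in truth.sites:
            window = text[site.center - 100 : site.center + 100]
            assert scan_sequence(window), f"no hit at {site.center}"

    def test_zero_sites_empty_truth(self):
        config = small_config(n_sites=0)
        genome, seqs, masks = simulate_genome(config)
        assert simulate_binding_landscape(config, genome, seqs).sites == []

    def test_min_spacing_respected(self):
        config = small_config(n_sites=100, chrom_length=500_000)
        genome, *_ = simulate_genome(config)
        truth = simulate_binding_landscape(config, genome)
        centers = sorted(s.center for s in truth.sites)
        assert min(np.diff(centers)) >= config.min_spacing

    def test_class_fractions_multinomial(self):
        config = small_config(n_sites=600, chrom_length=2_000_000)
        genome, *_ = simulate_genome(config)
        truth = simulate_binding_landscape(config, genome)
        counts = collections.Counter(s.klass for s in truth.sites)
        assert counts["shared"] / 600 == pytest.approx(0.6, abs=0.07)

    def test_genome_too_small_rejected(self):
        config = small_config(n_sites=500, chrom_length=100_000)
        genome, *_ = simulate_genome(config)
        with pytest.raises(ValueError):
            simulate_binding_landscape(config, genome)


class TestCoverage:
    def test_expected_total_reads_within_3sd(self):
        config = small_config(chrom_length=1_000_000, n_sites=50)
        genome, *_ = simulate_genome(config)
        truth = simulate_binding_landscape(config, genome)
        reads = simulate_coverage(truth, config, genome, "A")
        n_kb = 1000
        n_bound = len(truth.sites_bound_by("A"))
        expected = n_kb * config.background_rate + n_bound * config.enrichment
        # var: NB per kb + Poisson per site
        var = n_kb * (config.background_rate + config.nb_dispersion *
                      config.background_rate ** 2) + n_bound * config.enrichment
        assert abs(len(reads) - expected) <= 3 * np.sqrt(var)

    def test_igg_background_only(self):
        config = small_config(chrom_length=500_000)
        genome, *_ = simulate_genome(config)
        truth = simulate_binding_landscape(config, genome)
        igg = simulate_coverage(truth, config, genome, "IgG")
        # no site should show systematic IgG pile-up above background
        cov = coverage_from_intervals(igg, genome)
        at_sites = np.mean([cov["chr1"][s.center] for s in truth.sites])
        assert at_sites <= 3 * config.background_rate * config.read_length / 1000 + 1

    def test_zero_enrichment_matches_igg_rate(self):
        # factor track with enrichment 0 is statistically background-only
        hits = 0
        for seed in range(10):
            config = small_config(seed=seed, enrichment=0.0, chrom_length=200_000)
            genome, *_ = simulate_genome(config)
            truth = simulate_binding_landscape(config, genome)
            n_a = len(simulate_coverage(truth, config, genome, "A"))
            n_igg = len(simulate_coverage(truth, config, genome, "IgG"))
            p = stats.poisson.sf(
                max(n_a, n_igg) - 1, (n_a + n_igg) / 2
            )  # crude two-sample rate check
            if p > 0.01:
                hits += 1
        assert hits >= 8

    def test_no_background_reads_near_site_center(self):
        config = small_config(
            background_rate=0.0, n_sites=1, enrichment=50.0, chrom_length=100_000
        )
        genome, *_ = simulate_genome(config)
        truth = simulate_binding_landscape(config, genome)
        reads = simulate_coverage(truth, config, genome, "A")
        center = truth.sites[0].center
        for iv in reads:
            mid = (iv.start + iv.end) / 2
            assert abs(mid - center) <= 4 * config.site_read_sd + config.read_length


class TestCallers:
    def test_noiseless_callers_agree_exactly(self):
        config = small_config(
            caller_sensitivity=1.0, caller_jitter_sd=0.0, caller_fp_rate=0.0
        )
        genome, *_ = simulate_genome(config)
        truth = simulate_binding_landscape(config, genome)
        outs = simulate_caller_outputs(truth, config, genome, "A")
        assert outs[0] == outs[1] == outs[2]
        assert len(outs[0]) == len(truth.sites_bound_by("A"))

    def test_zero_sensitivity_only_false_positives(self):
        config = small_config(caller_sensitivity=0.0, caller_fp_rate=0.0)
        genome, *_ = simulate_genome(config)
        truth = simulate_binding_landscape(config, genome)
        outs = simulate_caller_outputs(truth, config, genome, "A")
        assert all(len(o) == 0 for o in outs)

    def test_two_of_three_coverage_matches_binomial(self):
        # P(>=2 of 3 callers) = 3 p^2 (1-p) + p^3 = 0.972 at p = 0.9
        p = 0.9
        covered = total = 0
        for seed in range(5):
            config = small_config(
                seed=seed, n_sites=200, chrom_length=1_000_000,
                caller_sensitivity=p, caller_fp_rate=0.0,
            )
            genome, *_ = simulate_genome(config)
            truth = simulate_binding_landscape(config, genome)
            outs = simulate_caller_outputs(truth, config, genome, "A")
            for site in truth.sites_bound_by("A"):
                n = sum(
                    any(pk.start <= site.center < pk.end for pk in out)
                    for out in outs
                )
                covered += n >= 2
                total += 1
        expected = 3 * p**2 * (1 - p) + p**3
        assert covered / total == pytest.approx(expected, abs=0.02)


class TestGenes:
    def test_non_overlapping_and_count(self):
        config = small_config(n_genes=25, chrom_length=500_000)
        genome, *_ = simulate_genome(config)
        genes = simulate_gene_annotation(config, genome)
        assert len(genes) == 25
        ivs = sorted((g.interval.start, g.interval.end) for g in genes)
        assert all(a[1] <= b[0] for a, b in zip(ivs, ivs[1:]))

    def test_strand_balance(self):
        n_plus = n = 0
        for seed in range(20):
            config = small_config(seed=seed, n_genes=20, chrom_length=500_000)
            genome, *_ = simulate_genome(config)
            for g in simulate_gene_annotation(config, genome):
                n_plus += g.interval.strand == "+"
                n += 1
        # binomial 99% interval around 0.5 for n~400
        assert abs(n_plus / n - 0.5) <= 2.58 * 0.5 / np.sqrt(n)


class TestTruthRoundTrip:
    def test_lossless(self, tmp_path):
        config = small_config()
        ds = simulate_all(config)
        write_truth(ds.truth, tmp_path / "s.tsv", tmp_path / "fp.tsv")
        back = read_truth(tmp_path / "s.tsv", tmp_path / "fp.tsv")
        assert back.sites == ds.truth.sites
        assert back.caller_false_positives == {
            k: v for k, v in ds.truth.caller_false_positives.items() if v
        } or back.caller_false_positives == ds.truth.caller_false_positives

    def test_full_dataset_deterministic(self, tmp_path):
        config = small_config(chrom_length=100_000, n_sites=20, n_genes=5)
        p1 = simulate_dataset(config, tmp_path / "x")
        p2 = simulate_dataset(config, tmp_path / "y")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key
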