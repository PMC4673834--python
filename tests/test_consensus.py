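"""Consensus-region calling, NB background model, scoring and filtering."""

import numpy as np
import pytest

from cobindseq.consensus import (
    ConsensusRegion,
    ModelError,
    NBBackground,
    adjust_pvalues_bh,
    call_consensus_regions,
    filter_binding_sites,
    fit_background_model,
    nb_survival,
    score_region,
    sum_binary_tracks,
)
from cobindseq.genome import (
    CoverageTrack,
    GenomeIndex,
    GenomicInterval,
    ReadIndex,
    binarize_occupancy,
    coverage_from_intervals,
)
from conftest import random_peaks
from oracles import brute_consensus, naive_bh, poisson_upper_tail


def _tracks(genome, *peak_lists):
    return [binarize_occupancy(peaks, genome) for peaks in peak_lists]


class TestSummedTracks:
    def test_overlap_arithmetic(self, genome_10kb):
        tracks = _tracks(
            genome_10kb,
            [GenomicInterval("chr1", 100, 400)],
            [GenomicInterval("chr1", 250, 600)],
        )
        summed = sum_binary_tracks(tracks)
        assert (summed["chr1"][250:400] == 2).all()
        assert summed["chr1"].max() == 2

    def test_single_track_identity(self, genome_10kb):
        (track,) = _tracks(genome_10kb, [GenomicInterval("chr1", 0, 500)])
        summed = sum_binary_tracks([track])
        assert (summed["chr1"] == track["chr1"]).all()

    def test_three_identical_tracks_linear(self, genome_10kb):
        tracks = _tracks(genome_10kb, *[[GenomicInterval("chr1", 100, 200)]] * 3)
        assert sum_binary_tracks(tracks)["chr1"].max() == 3

    def test_genome_mismatch_rejected(self, genome_10kb, genome_two_chrom):
        t1 = _tracks(genome_10kb, [GenomicInterval("chr1", 0, 100)])[0]
        t2 = _tracks(genome_two_chrom, [GenomicInterval("chr1", 0, 100)])[0]
        with pytest.raises(ValueError):
            sum_binary_tracks([t1, t2])


class TestConsensusRegions:
    def test_exact_150bp_region_kept(self, genome_10kb):
        tracks = _tracks(
            genome_10kb,
            [GenomicInterval("chr1", 100, 400)],
            [GenomicInterval("chr1", 250, 600)],
            [],
        )
        regions = call_consensus_regions(sum_binary_tracks(tracks))
        assert [(r.start, r.end) for r in regions] == [(250, 400)]

    def test_single_caller_yields_nothing(self, genome_10kb):
        tracks = _tracks(genome_10kb, [GenomicInterval("chr1", 0, 5000)], [])
        assert call_consensus_regions(sum_binary_tracks(tracks)) == []

    def test_short_run_dropped(self, genome_10kb):
        tracks = _tracks(
            genome_10kb,
            [GenomicInterval("chr1", 0, 100)],
            [GenomicInterval("chr1", 50, 140)],
        )
        assert call_consensus_regions(sum_binary_tracks(tracks)) == []

    def test_matches_brute_force_on_random_instances(self, rng):
        genome = GenomeIndex([("chr1", 10_000)])
        for _ in range(15):
            peak_lists = [random_peaks(rng, 10_000, int(rng.integers(3, 12)))
                          for _ in range(3)]
            summed = sum_binary_tracks(_tracks(genome, *peak_lists))
            fast = [(r.chrom, r.start, r.end)
                    for r in call_consensus_regions(summed)]
            slow = brute_consensus(
                [[(p.chrom, p.start, p.end) for p in pl] for pl in peak_lists],
                {"chr1": 10_000},
            )
            assert fast == slow

    def test_invariant_under_caller_order(self, rng):
        genome = GenomeIndex([("chr1", 10_000)])
        peak_lists = [random_peaks(rng, 10_000, 8) for _ in range(3)]
        a = call_consensus_regions(sum_binary_tracks(_tracks(genome, *peak_lists)))
        b = call_consensus_regions(
            sum_binary_tracks(_tracks(genome, *peak_lists[::-1]))
        )
        assert a == b


def _coverage_from_bin_counts(genome, counts, bin_size=1000, read_length=200):
    """Coverage whose bin read counts are exactly `counts` (reads inside bins)."""
    ivs = []
    for b, c in enumerate(counts):
        for r in range(int(c)):
            s = b * bin_size + (r % 4) * read_length
            ivs.append(GenomicInterval("chr1", s, s + read_length))
    return coverage_from_intervals(ivs, genome)


class TestBackgroundModel:
    def test_identical_tracks_scale_one(self):
        genome = GenomeIndex([("chr1", 50_000)])
        counts = np.full(50, 5)
        cov = _coverage_from_bin_counts(genome, counts)
        bg = fit_background_model(cov, cov)
        assert bg.scale == pytest.approx(1.0)
        assert bg.mean == pytest.approx(5.0)

    def test_double_control_scale_half(self):
        genome = GenomeIndex([("chr1", 50_000)])
        sample = _coverage_from_bin_counts(genome, np.full(50, 4))
        control = _coverage_from_bin_counts(genome, np.full(50, 8))
        assert fit_background_model(sample, control).scale == pytest.approx(0.5)

    def test_nb_moments_recovered_within_15pct(self):
        rng = np.random.default_rng(7)
        n_bins, mean, disp = 2000, 5.0, 0.2
        genome = GenomeIndex([("chr1", n_bins * 1000)])
        size = 1.0 / disp
        counts = rng.negative_binomial(size, size / (size + mean), n_bins)
        sample = _coverage_from_bin_counts(genome, counts)
        control = _coverage_from_bin_counts(genome, np.full(n_bins, int(mean)))
        bg = fit_background_model(sample, control)
        assert bg.mean == pytest.approx(mean, rel=0.15)
        assert bg.dispersion == pytest.approx(disp, rel=0.15)

    def test_excluded_bins_ignored(self):
        genome = GenomeIndex([("chr1", 100_000)])
        counts = np.full(100, 3)
        counts[:10] = 500  # contaminated bins to be excluded
        sample = _coverage_from_bin_counts(genome, counts)
        control = _coverage_from_bin_counts(genome, np.full(100, 3))
        bg = fit_background_model(
            sample, control, exclude=[GenomicInterval("chr1", 0, 10_000)]
        )
        assert bg.mean == pytest.approx(3.0)

    def test_too_few_bins_rejected(self):
        genome = GenomeIndex([("chr1", 10_000)])
        cov = _coverage_from_bin_counts(genome, np.full(10, 3))
        with pytest.raises(ModelError):
            fit_background_model(cov, cov)

    def test_zero_control_rejected(self):
        genome = GenomeIndex([("chr1", 50_000)])
        sample = _coverage_from_bin_counts(genome, np.full(50, 3))
        control = CoverageTrack.zeros(genome)
        with pytest.raises(ModelError):
            fit_background_model(sample, control)


class TestScoring:
    def _setup(self, genome, sample_reads, control_reads):
        return (
            ReadIndex(sample_reads, genome),
            ReadIndex(control_reads, genome),
        )

    def test_null_consistent_region_not_significant(self, genome_10kb):
        # observed equals the expected background level -> p stays large
        bg = NBBackground(bin_size=1000, mean=5.0, dispersion=0.2, scale=1.0)
        region = GenomicInterval("chr1", 0, 1000)
        reads = [GenomicInterval("chr1", 100 * i, 100 * i + 200) for i in range(5)]
        s_idx, c_idx = self._setup(genome_10kb, reads, reads)
        rc, cc, fc, p = score_region(region, s_idx, c_idx, bg)
        assert rc == 5
        assert fc == pytest.approx(1.0)
        assert p >= 0.3

    def test_poisson_limit_matches_closed_form(self, genome_10kb):
        bg = NBBackground(bin_size=1000, mean=2.0, dispersion=0.0, scale=1.0)
        region = GenomicInterval("chr1", 0, 1000)
        reads = [GenomicInterval("chr1", 10 * i, 10 * i + 200) for i in range(10)]
        s_idx, c_idx = self._setup(genome_10kb, reads, [])
        rc, cc, fc, p = score_region(region, s_idx, c_idx, bg)
        assert rc == 10
        assert p == pytest.approx(poisson_upper_tail(10, 2.0), rel=1e-10)

    def test_zero_observed_is_null(self, genome_10kb):
        bg = NBBackground(bin_size=1000, mean=2.0, dispersion=0.1, scale=1.0)
        region = GenomicInterval("chr1", 5000, 6000)
        control = [GenomicInterval("chr1", 5000, 5200) for _ in range(4)]
        s_idx, c_idx = self._setup(genome_10kb, [], control)
        rc, cc, fc, p = score_region(region, s_idx, c_idx, bg)
        assert rc == 0
        assert p == pytest.approx(1.0)
        assert fc <= 1.0

    def test_nb_survival_poisson_grid(self):
        from scipy import stats

        for lam in (0.5, 2.0, 7.3):
            for k in (0, 1, 5, 20):
                assert nb_survival(k, lam, 0.0) == pytest.approx(
                    poisson_upper_tail(k, lam), rel=1e-10
                )
        # dispersion > 0 has heavier tails than Poisson
        assert nb_survival(20, 2.0, 0.5) > nb_survival(20, 2.0, 0.0)


class TestBH:
    def test_closed_form_triplet(self):
        np.testing.assert_allclose(
            adjust_pvalues_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        assert adjust_pvalues_bh([0.2])[0] == pytest.approx(0.2)

    def test_matches_naive_oracle_on_random_vectors(self, rng):
        for _ in range(100):
            p = rng.random(int(rng.integers(1, 40)))
            np.testing.assert_allclose(adjust_pvalues_bh(p), naive_bh(list(p)),
                                       atol=1e-12)

    def test_q_at_least_p_and_order_preserved(self, rng):
        p = rng.random(200)
        q = adjust_pvalues_bh(p)
        assert (q >= p - 1e-15).all()
        # monotone in p-rank
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues_bh([0.5, 1.5])


class TestFilters:
    def _region(self, reads, fc, q):
        return ConsensusRegion(
            interval=GenomicInterval("chr1", 0, 200), support=2,
            read_count=reads, control_count=1, fold_change=fc,
            p_value=q / 2, q_value=q,
        )

    @pytest.mark.parametrize(
        "reads,fc,q,kept",
        [
            (9, 5.0, 1e-6, False),   # too few reads
            (50, 1.5, 1e-6, False),  # fold change below 2
            (50, 4.0, 0.005, True),  # passes all three
            (10, 2.0, 0.01, True),   # thresholds are inclusive
            (50, 4.0, 0.02, False),  # q above threshold
        ],
    )
    def test_threshold_logic(self, reads, fc, q, kept):
        sites = filter_binding_sites([self._region(reads, fc, q)])
        assert (len(sites) == 1) == kept
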