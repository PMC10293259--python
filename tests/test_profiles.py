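import numpy as np
import pytest

from exchseq.core import Genome
from exchseq.preprocess import PointSet
from exchseq.profiles import (anchored_matrix, bin_by_covariate,
                              scaled_gene_matrix, scaled_region_matrix,
                              select_heterochromatin_regions, smooth_trend,
                              tile_genome, top_fraction)

from conftest import make_regions


def point_set(genome, **by_chrom):
    return PointSet({k: np.sort(np.asarray(v, dtype=np.int64))
                     for k, v in by_chrom.items()}, genome)


class TestTileGenome:
    def test_exact_division(self):
        g = Genome(("c",), (10_000,))
        assert len(tile_genome(g, 5000)) == 2

    def test_partial_half_rule(self):
        g = Genome(("c",), (12_600,))
        tiles = tile_genome(g, 5000, partial="half")
        assert len(tiles) == 3
        assert tiles[2].end - tiles[2].start == 2600
        assert len(tile_genome(g, 5000, partial="never")) == 2

    def test_partial_below_half_dropped(self):
        g = Genome(("c",), (12_400,))
        assert len(tile_genome(g, 5000, partial="half")) == 2
        assert len(tile_genome(g, 5000, partial="always")) == 3

    def test_tiles_partition_chromosomes(self, tiny_genome):
        tiles = tile_genome(tiny_genome, 3000, partial="always")
        for chrom, length in tiny_genome.sizes.items():
            sub = tiles.df[tiles.df["chrom"] == chrom]
            assert sub["start"].iloc[0] == 0
            assert sub["end"].iloc[-1] == length
            assert (sub["start"].to_numpy()[1:]
                    == sub["end"].to_numpy()[:-1]).all()


class TestAnchoredMatrix:
    def test_column_count(self, tiny_genome):
        anchors = make_regions([("chr1", 4000, 4100)], tiny_genome)
        pts = point_set(tiny_genome, chr1=[4000, 4050])
        mat = anchored_matrix(pts, anchors, flank_bp=1000, bin_bp=50)
        assert mat.n_bins == 40

    def test_counts_land_in_expected_bins(self, tiny_genome):
        anchors = make_regions([("chr1", 4000, 4100)], tiny_genome)  # c=4050
        pts = point_set(tiny_genome, chr1=[3050, 4049, 4050, 5049])
        mat = anchored_matrix(pts, anchors, 1000, 50)
        counts = mat.values[0] * 50 / 1000  # back to raw counts
        assert counts[0] == 1  # 3050 in [3050,3100)
        assert counts[19] == 1 and counts[20] == 1  # just below/at center
        assert counts[39] == 1  # 5049 in last bin

    def test_strand_aware_equals_reversed_unstranded_for_minus(self,
                                                               tiny_genome):
        rng = np.random.default_rng(0)
        anchors = make_regions([("chr1", 3000, 3100, "-"),
                                ("chr1", 6000, 6050, "-")], tiny_genome)
        pts = point_set(tiny_genome, chr1=rng.integers(2000, 8000, 500))
        plain = anchored_matrix(pts, anchors, 1000, 50, strand_aware=False)
        aware = anchored_matrix(pts, anchors, 1000, 50, strand_aware=True)
        assert np.array_equal(aware.values, plain.values[:, ::-1])

    def test_strand_reversal_is_involution(self, tiny_genome):
        rng = np.random.default_rng(1)
        anchors = make_regions([("chr1", 3000, 3100, "-"),
                                ("chr1", 6000, 6100, "+")], tiny_genome)
        pts = point_set(tiny_genome, chr1=rng.integers(2000, 8000, 300))
        aware = anchored_matrix(pts, anchors, 1000, 50, strand_aware=True)
        again = aware.values.copy()
        minus = anchors.strands == "-"
        again[minus] = again[minus, ::-1]
        again[minus] = again[minus, ::-1]
        assert np.array_equal(again, aware.values)


class TestScaledGeneMatrix:
    def test_always_120_columns(self, mb_genome):
        genes = make_regions([("chr1", 50_000, 60_000, "+"),
                              ("chr1", 200_000, 202_000, "-")], mb_genome)
        pts = point_set(mb_genome, chr1=np.arange(40_000, 220_000, 97))
        mat = scaled_gene_matrix(pts, genes)
        assert mat.values.shape == (2, 120)

    def test_uniform_coverage_gives_flat_rows(self, mb_genome):
        genes = make_regions([("chr1", 100_000, 150_000, "+")], mb_genome)
        pts = point_set(mb_genome, chr1=np.arange(90_000, 160_000, 10))
        mat = scaled_gene_matrix(pts, genes)
        row = mat.values[0]
        assert row.std() / row.mean() < 0.05

    def test_minus_gene_equals_mirrored_plus_computation(self, mb_genome):
        """A minus-strand gene's profile equals the plus-strand profile of
        the mirror-image point configuration."""
        L = 1_000_000
        rng = np.random.default_rng(2)
        pts_fwd = np.sort(rng.integers(80_000, 180_000, 400))
        gene_minus = make_regions([("chr1", 100_000, 160_000, "-")],
                                  mb_genome)
        gene_plus = make_regions(
            [("chr1", L - 160_000, L - 100_000, "+")], mb_genome)
        mirrored = np.sort(L - 1 - pts_fwd)
        m_minus = scaled_gene_matrix(point_set(mb_genome, chr1=pts_fwd),
                                     gene_minus)
        m_plus = scaled_gene_matrix(point_set(mb_genome, chr1=mirrored),
                                    gene_plus)
        # mirror maps position x to L-1-x; bin contents may shift by one
        # base at edges, so compare within a tolerance of one point per bin
        assert np.abs(m_minus.values - m_plus.values).max() <= 1000 / 500

    def test_short_gene_rejected(self, mb_genome):
        genes = make_regions([("chr1", 1000, 1050, "+")], mb_genome)
        with pytest.raises(ValueError, match=">= 100"):
            scaled_gene_matrix(point_set(mb_genome, chr1=[1010]), genes)

    def test_element_body_window_count(self, mb_genome):
        regions = make_regions([("chr1", 50_000, 55_000, "+")], mb_genome)
        pts = point_set(mb_genome, chr1=np.arange(45_000, 60_000, 50))
        mat = scaled_region_matrix(pts, regions, flank_bp=2500,
                                   flank_bins=5, body_bins=250)
        assert mat.n_bins == 5 + 250 + 5


class TestBinByCovariate:
    def test_equal_division(self, mb_genome):
        regions = make_regions([("chr1", i * 100, i * 100 + 50)
                                for i in range(100)], mb_genome)
        bins = bin_by_covariate(regions, np.arange(100), 4)
        assert [b.count for b in bins] == [25, 25, 25, 25]

    def test_remainder_spread_over_leading_bins(self, mb_genome):
        regions = make_regions([("chr1", i * 100, i * 100 + 50)
                                for i in range(10)], mb_genome)
        bins = bin_by_covariate(regions, np.arange(10), 3)
        assert [b.count for b in bins] == [4, 3, 3]

    def test_mean_covariate_monotone_and_membership_conserved(self,
                                                              mb_genome):
        rng = np.random.default_rng(3)
        n = 137
        regions = make_regions([("chr1", i * 100, i * 100 + 50)
                                for i in range(n)], mb_genome)
        cov = rng.normal(size=n)
        bins = bin_by_covariate(regions, cov, 7)
        means = [b.mean_covariate for b in bins]
        assert (np.diff(means) >= 0).all()
        assert sum(b.count for b in bins) == n
        all_members = np.concatenate([b.member_index for b in bins])
        assert sorted(all_members) == list(range(n))

    def test_coverage_filter_applied_before_binning(self, mb_genome):
        regions = make_regions([("chr1", i * 100, i * 100 + 50)
                                for i in range(20)], mb_genome)
        coverage = np.array([0.0] * 5 + [1.0] * 15)
        bins = bin_by_covariate(regions, np.arange(20), 3,
                                coverage=coverage, min_coverage=0.5)
        assert sum(b.count for b in bins) == 15

    def test_per_bin_channel_means(self, mb_genome):
        regions = make_regions([("chr1", i * 100, i * 100 + 50)
                                for i in range(6)], mb_genome)
        e = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        bins = bin_by_covariate(regions, np.arange(6), 2, values={"E": e})
        assert bins[0].means["E"] == 1.0 and bins[1].means["E"] == 4.0


class TestSmoothTrend:
    def test_linear_input_recovered_exactly(self):
        x = np.linspace(0, 1, 50)
        assert np.abs(smooth_trend(x, x) - x).max() < 1e-6

    def test_constant_input(self):
        x = np.linspace(0, 1, 30)
        assert np.allclose(smooth_trend(x, np.full(30, 2.5)), 2.5)

    def test_noisy_linear_slope_within_ten_percent(self):
        rng = np.random.default_rng(4)
        x = np.linspace(0, 10, 200)
        y = 3.0 * x + rng.normal(0, 1.0, 200)
        fit = smooth_trend(x, y)
        slope = np.polyfit(x, fit, 1)[0]
        assert slope == pytest.approx(3.0, rel=0.10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            smooth_trend(np.arange(5), np.arange(5))


class TestTopFraction:
    def test_whole_set(self, mb_genome):
        regions = make_regions([("chr1", i, i + 10) for i in
                                range(0, 500, 100)], mb_genome)
        assert len(top_fraction(regions, np.arange(5), 1.0)) == 5

    def test_ceiling_rule(self, mb_genome):
        regions = make_regions([("chr1", i * 20, i * 20 + 10)
                                for i in range(200)], mb_genome)
        assert len(top_fraction(regions, np.arange(200), 0.01)) == 2

    def test_matches_sort_and_slice_oracle(self, mb_genome):
        rng = np.random.default_rng(5)
        n = 57
        regions = make_regions([("chr1", i * 20, i * 20 + 10)
                                for i in range(n)], mb_genome)
        score = rng.normal(size=n)
        got = top_fraction(regions, score, 0.25)
        k = int(np.ceil(0.25 * n))
        want = set(np.argsort(-score, kind="stable")[:k])
        got_idx = set(got.starts // 20)
        assert got_idx == want


class TestHeterochromatinSelection:
    def test_length_window_inclusive(self, mb_genome):
        peaks = make_regions([("chr1", 0, 100), ("chr1", 200, 350),
                              ("chr1", 1000, 3000), ("chr1", 5000, 5149)],
                             mb_genome)
        dens = np.array([9.0, 1.0, 2.0, 3.0])
        out = select_heterochromatin_regions(peaks, dens, 150, 2000, 10)
        assert len(out) == 2  # 150 and 2000 bp kept; 100 and 149 dropped

    def test_top_n_by_density(self, mb_genome):
        peaks = make_regions([("chr1", i * 1000, i * 1000 + 500)
                              for i in range(5)], mb_genome)
        dens = np.array([1.0, 5.0, 3.0, 4.0, 2.0])
        out = select_heterochromatin_regions(peaks, dens, top_n=2)
        assert set(out.starts) == {1000, 3000}
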