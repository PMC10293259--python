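import numpy as np
import pandas as pd
import pytest

from exchseq.core import (BedParseError, Genome, GenomicInterval,
                          overlap_flags, promoters, read_bed, read_fragments,
                          read_gene_table, shift_regions, write_bed,
                          write_fragment_bed)

from conftest import brute_force_overlaps, make_fragments, make_regions


class TestGenome:
    def test_chrom_sizes_round_trip(self, tiny_genome, tmp_path):
        p = tmp_path / "g.chrom.sizes"
        tiny_genome.write_chrom_sizes(p)
        assert Genome.read_chrom_sizes(p) == tiny_genome

    @pytest.mark.parametrize("names,lengths", [
        (("chr1", "chr1"), (10, 10)),  # duplicate names
        (("chr1",), (0,)),  # non-positive length
        (("chr1", "chr2"), (10,)),  # mismatched
    ])
    def test_invalid_genomes_rejected(self, names, lengths):
        with pytest.raises(ValueError):
            Genome(names, lengths)


class TestIntervalInvariants:
    def test_half_open_validation(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 200, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)
        assert len(GenomicInterval("chr1", 100, 200)) == 100

    def test_regionset_rejects_inverted_interval(self, tiny_genome):
        with pytest.raises(ValueError, match="start >= end"):
            make_regions([("chr1", 200, 100)], tiny_genome)

    def test_regionset_rejects_out_of_bounds(self, tiny_genome):
        with pytest.raises(ValueError):
            make_regions([("chr1", 9_000, 11_000)], tiny_genome)


class TestBedIO:
    def test_bed6_line_maps_to_interval(self, tmp_path, tiny_genome):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\tx\t0\t+\n")
        rs = read_bed(p, tiny_genome)
        assert len(rs) == 1
        iv = rs[0]
        assert (iv.chrom, iv.start, iv.end, iv.strand) == ("chr1", 100, 200,
                                                           "+")

    def test_inverted_interval_is_parse_error_with_line(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\t200\nchr1\t200\t100\n")
        with pytest.raises(BedParseError, match="line 2"):
            read_bed(p)

    def test_round_trip_byte_identical(self, tmp_path, tiny_genome):
        p = tmp_path / "a.bed"
        content = ("chr1\t100\t200\ta\t5\t+\n"
                   "chr2\t0\t50\tb\t0\t-\n"
                   "chr1\t300\t400\tc\t2\t.\n")
        p.write_text(content)
        rs = read_bed(p, tiny_genome)
        out = tmp_path / "b.bed"
        write_bed(rs, out)
        assert out.read_text() == content
        assert len(rs) == 3  # order preserved; sortable on request
        assert list(rs.sorted().chroms) == ["chr1", "chr1", "chr2"]

    def test_unknown_chromosome_skip_or_fail(self, tmp_path, tiny_genome):
        p = tmp_path / "a.bed"
        p.write_text("chrX\t0\t10\nchr1\t0\t10\n")
        with pytest.raises(BedParseError, match="chrX"):
            read_bed(p, tiny_genome)
        rs = read_bed(p, tiny_genome, on_unknown_chrom="skip")
        assert len(rs) == 1 and rs[0].chrom == "chr1"


class TestReadFragments:
    MQS = [9, 10, 11, 30, 0]

    def _write_fragment_bed(self, path):
        lines = [f"chr1\t{100 * i}\t{100 * i + 80}\tf{i}\t{mq}\t+"
                 for i, mq in enumerate(self.MQS)]
        path.write_text("\n".join(lines) + "\n")

    def _write_sam(self, path):
        lines = ["@HD\tVN:1.6\tSO:coordinate", "@SQ\tSN:chr1\tLN:10000"]
        for i, mq in enumerate(self.MQS):
            s = 100 * i
            lines.append(f"t{i}\t99\tchr1\t{s + 1}\t{mq}\t80M\t=\t{s + 1}\t80"
                         f"\t*\t*")
            lines.append(f"t{i}\t147\tchr1\t{s + 1}\t{mq}\t80M\t=\t{s + 1}"
                         f"\t-80\t*\t*")
        path.write_text("\n".join(lines) + "\n")

    def test_mapq_filter_counts(self, tmp_path):
        p = tmp_path / "f.bed"
        self._write_fragment_bed(p)
        assert len(read_fragments(p, min_mapq=10)) == 3
        assert len(read_fragments(p, min_mapq=0)) == 5

    def test_sam_and_bed_dialects_agree(self, tmp_path):
        bed = tmp_path / "f.bed"
        sam = tmp_path / "f.sam"
        self._write_fragment_bed(bed)
        self._write_sam(sam)
        a = read_fragments(bed, min_mapq=10).df
        b = read_fragments(sam, min_mapq=10).df
        pd.testing.assert_frame_equal(
            a.sort_values("start", ignore_index=True),
            b.sort_values("start", ignore_index=True),
            check_dtype=False)

    def test_fragment_bed_round_trip(self, tmp_path):
        frags = make_fragments([("chr1", 0, 160, "+", 60),
                                ("chr1", 50, 230, "-", 12)])
        p = tmp_path / "w.bed"
        write_fragment_bed(frags, p)
        back = read_fragments(p, min_mapq=0)
        pd.testing.assert_frame_equal(frags.df, back.df, check_dtype=False)


class TestShiftRegions:
    def test_translation(self, mb_genome):
        rs = make_regions([("chr1", 100, 200)], mb_genome)
        out = shift_regions(rs, 20_000, mb_genome)
        assert (out[0].start, out[0].end) == (20_100, 20_200)

    def test_zero_shift_identity(self, mb_genome):
        rs = make_regions([("chr1", 100, 200), ("chr1", 5_000, 6_000)],
                          mb_genome)
        out = shift_regions(rs, 0, mb_genome)
        pd.testing.assert_frame_equal(out.df, rs.df)

    def test_out_of_bounds_dropped_and_counted(self, mb_genome):
        rs = make_regions([("chr1", 999_400, 999_500),  # 500 bp before end
                           ("chr1", 100, 200)], mb_genome)
        out = shift_regions(rs, 20_000, mb_genome)
        assert len(out) == 1
        assert out.dropped == 1

    def test_strand_aware_mode_moves_minus_upstream(self, mb_genome):
        rs = make_regions([("chr1", 50_000, 50_100, "-")], mb_genome)
        out = shift_regions(rs, 20_000, mb_genome, strand_aware=True)
        assert out[0].start == 30_000


class TestOverlapFlags:
    def test_basic_overlap(self, tiny_genome):
        a = make_regions([("chr1", 100, 200)], tiny_genome)
        b = make_regions([("chr1", 150, 160)], tiny_genome)
        assert overlap_flags(a, b).tolist() == [True]

    def test_adjacent_half_open_do_not_overlap(self, tiny_genome):
        a = make_regions([("chr1", 100, 200)], tiny_genome)
        b = make_regions([("chr1", 200, 300)], tiny_genome)
        assert overlap_flags(a, b).tolist() == [False]
        assert overlap_flags(b, a).tolist() == [False]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("min_ov", [1, 25])
    def test_matches_quadratic_oracle(self, tiny_genome, seed, min_ov):
        rng = np.random.default_rng(seed)

        def random_set(n):
            rows = []
            for _ in range(n):
                chrom = "chr1" if rng.random() < 0.6 else "chr2"
                start = int(rng.integers(0, 7_800))
                end = start + int(rng.integers(1, 150))
                rows.append((chrom, start, end))
            return make_regions(rows, tiny_genome)

        regions, other = random_set(40), random_set(15)
        got = overlap_flags(regions, other, min_overlap_bp=min_ov)
        want = brute_force_overlaps(regions, other, min_overlap=min_ov)
        assert np.array_equal(got, want)


class TestGeneTable:
    def _write(self, path, rows):
        header = "gene_id\tchrom\tstart\tend\tstrand\texpression\n"
        body = "".join("\t".join(map(str, r)) + "\n" for r in rows)
        path.write_text(header + body)

    def test_short_transcripts_discarded(self, tmp_path, tiny_genome):
        p = tmp_path / "genes.tsv"
        self._write(p, [("g1", "chr1", 0, 5000, "+", 2.0),
                        ("g2", "chr1", 6000, 7500, "-", 1.0)])  # 1.5 kb
        genes = read_gene_table(p, tiny_genome)
        assert list(genes.metadata("gene_id")) == ["g1"]
        assert len(read_gene_table(p, tiny_genome, min_length=0)) == 2

    def test_promoters_are_1kb_upstream_of_tss(self, tmp_path, tiny_genome):
        p = tmp_path / "genes.tsv"
        self._write(p, [("g1", "chr1", 2000, 5000, "+", 1.0),
                        ("g2", "chr1", 2000, 5000, "-", 1.0)])
        prom = promoters(read_gene_table(p, tiny_genome))
        assert (prom[0].start, prom[0].end) == (1000, 2000)  # + : before start
        assert (prom[1].start, prom[1].end) == (5000, 6000)  # - : after end
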