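"""Interval arithmetic, the strand-aware intersection engine and file I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from endosirna import (
    ClassificationError,
    ExonBin,
    GenomicInterval,
    ParseError,
    classify_exon_bin,
    intersect,
    read_bed,
    read_bedgraph,
    read_gene_models,
    write_bed,
    write_bedgraph,
    write_gtf,
)
from endosirna.intervals import BedRecord

from conftest import brute_force_intersect, make_gene, random_intervals


class TestGenomicInterval:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(chrom="", start=0, end=10),
            dict(chrom="chr1", start=-1, end=10),
            dict(chrom="chr1", start=10, end=10),
            dict(chrom="chr1", start=10, end=5),
            dict(chrom="chr1", start=0, end=10, strand="x"),
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GenomicInterval(**kwargs)

    def test_half_open_overlap(self):
        a = GenomicInterval("chr1", 100, 120, "+")
        assert a.overlap_bp(GenomicInterval("chr1", 119, 140, "+")) == 1
        assert a.overlap_bp(GenomicInterval("chr1", 120, 140, "+")) == 0  # abutting
        assert a.overlap_bp(a) == 20
        assert a.overlap_bp(GenomicInterval("chr2", 100, 120)) == 0


class TestIntersect:
    def test_boundary_cases(self):
        a = [GenomicInterval("chr1", 100, 120, "+")]
        assert [(r.a_index, r.b_index, r.overlap_bp) for r in
                intersect(a, [GenomicInterval("chr1", 119, 140, "+")])] == [(0, 0, 1)]
        assert len(intersect(a, [GenomicInterval("chr1", 120, 140, "+")])) == 0

    @pytest.mark.parametrize("bad", [0, -1, 1.5])
    def test_min_overlap_validation(self, bad):
        with pytest.raises(ValueError):
            intersect([], [], min_overlap_bp=bad)

    def test_unknown_strand_mode(self):
        with pytest.raises(ValueError):
            intersect([], [], strand_mode="both")

    def test_unstranded_pairs_skipped_and_tallied(self):
        a = [GenomicInterval("chr1", 0, 50, ".")]
        b = [GenomicInterval("chr1", 10, 40, "+")]
        res = intersect(a, b, strand_mode="same")
        assert len(res) == 0 and res.skipped_unstranded == 1
        assert len(intersect(a, b, strand_mode="ignore")) == 1

    @pytest.mark.parametrize("strand_mode", ["ignore", "same", "opposite"])
    @pytest.mark.parametrize("min_overlap_bp", [1, 5])
    def test_matches_brute_force_oracle(self, strand_mode, min_overlap_bp):
        rng = np.random.default_rng(42)
        a = random_intervals(rng, 50, chroms=("chrA", "chrB"))
        b = random_intervals(rng, 50, chroms=("chrA", "chrB"))
        res = intersect(a, b, strand_mode=strand_mode, min_overlap_bp=min_overlap_bp)
        expected, skipped = brute_force_intersect(a, b, strand_mode, min_overlap_bp)
        assert [(r.a_index, r.b_index, r.overlap_bp) for r in res] == sorted(expected)
        assert res.skipped_unstranded == skipped

    def test_output_sorted_and_deterministic(self):
        rng = np.random.default_rng(7)
        a = random_intervals(rng, 30)
        b = random_intervals(rng, 30)
        keys = [(r.a_index, r.b_index) for r in intersect(a, b)]
        assert keys == sorted(keys)
        assert keys == [(r.a_index, r.b_index) for r in intersect(a, b)]


class TestClassifyExonBin:
    def test_single_exon_gene(self, single_exon_gene):
        read = GenomicInterval("chr1", 150, 172, "+")
        assert classify_exon_bin(read, single_exon_gene) is ExonBin.SINGLE_EXON

    def test_minus_strand_reverses_bins(self, three_exon_minus):
        # genomically last exon of a minus-strand gene is its 5' first exon
        read = GenomicInterval("chr1", 520, 545, "+")
        assert classify_exon_bin(read, three_exon_minus) is ExonBin.FIRST_5P
        first = GenomicInterval("chr1", 120, 145, "+")
        assert classify_exon_bin(first, three_exon_minus) is ExonBin.LAST_3P

    def test_max_overlap_rule_at_boundary(self, three_exon_plus):
        # 15 bp in exon1, rest in the intron: exon1 wins outright
        read = GenomicInterval("chr1", 185, 210, "+")
        assert classify_exon_bin(read, three_exon_plus) is ExonBin.FIRST_5P

    def test_internal_exon(self, three_exon_plus):
        read = GenomicInterval("chr1", 310, 332, "+")
        assert classify_exon_bin(read, three_exon_plus) is ExonBin.INTERNAL

    def test_exact_tie_between_bins_is_other(self):
        gene = make_gene(exon_spans=((100, 200), (210, 310)))
        # 10 bp in each of the two exons
        read = GenomicInterval("chr1", 190, 220, "+")
        assert classify_exon_bin(read, gene) is ExonBin.OTHER

    def test_no_exon_overlap_raises(self, three_exon_plus):
        with pytest.raises(ClassificationError):
            classify_exon_bin(GenomicInterval("chr1", 250, 270, "+"), three_exon_plus)

    @given(offset=st.integers(0, 10_000), name=st.sampled_from(["chr1", "chr9", "scaffold_2"]))
    @settings(max_examples=25, derandomize=True)
    def test_invariant_under_translation_and_renaming(self, offset, name):
        gene = make_gene(chrom="chr1")
        read = GenomicInterval("chr1", 185, 210, "+")
        moved_exons = tuple((e.start + offset, e.end + offset) for e in gene.exons)
        moved_gene = make_gene(chrom=name, exon_spans=moved_exons)
        moved_read = GenomicInterval(name, read.start + offset, read.end + offset, "+")
        assert classify_exon_bin(read, gene) is classify_exon_bin(moved_read, moved_gene)

    SWAP = {ExonBin.FIRST_5P: ExonBin.LAST_3P, ExonBin.LAST_3P: ExonBin.FIRST_5P,
            ExonBin.INTERNAL: ExonBin.INTERNAL, ExonBin.OTHER: ExonBin.OTHER}

    @pytest.mark.parametrize("seed", range(5))
    def test_strand_flip_and_reflection_symmetries(self, seed):
        """Flipping the gene strand (coordinates fixed) swaps 5'<->3' bins;
        so does mirroring the coordinates (strand fixed); doing both at once
        therefore preserves the bin."""
        rng = np.random.default_rng(seed)
        gene = make_gene(strand="+")
        span = 1000
        start = int(rng.integers(100, 560))
        read = GenomicInterval("chr1", start, start + 25, "+")
        try:
            orig = classify_exon_bin(read, gene)
        except ClassificationError:
            return
        flipped_gene = make_gene(strand="-")
        assert classify_exon_bin(read, flipped_gene) is self.SWAP[orig]
        refl_exons = tuple(sorted((span - e.end, span - e.start) for e in gene.exons))
        refl_read = GenomicInterval("chr1", span - read.end, span - read.start, "+")
        refl_gene_same_strand = make_gene(strand="+", exon_spans=refl_exons)
        assert classify_exon_bin(refl_read, refl_gene_same_strand) is self.SWAP[orig]
        refl_gene_flipped = make_gene(strand="-", exon_spans=refl_exons)
        assert classify_exon_bin(refl_read, refl_gene_flipped) is orig


class TestFileIO:
    def test_bed_line_parsing(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("track name=x\n# comment\nchr1\t99\t120\tr1\t0\t+\n")
        (rec,) = read_bed(p)
        assert rec.interval == GenomicInterval("chr1", 99, 120, "+")
        assert rec.name == "r1"

    def test_malformed_bed_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t10\tok\t0\t+\nchr1\t50\tnope\n")
        with pytest.raises(ParseError, match="bad.bed:2"):
            read_bed(p)

    def test_bed_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(3)
        records = [BedRecord(iv, f"r{i}", float(i)) for i, iv in
                   enumerate(random_intervals(rng, 100))]
        p = tmp_path / "rt.bed"
        write_bed(p, records)
        assert [r.interval for r in read_bed(p)] == [r.interval for r in records]

    def test_bedgraph_round_trip(self, tmp_path):
        from endosirna import OccupancySegment
        segs = [OccupancySegment(GenomicInterval("chr1", 0, 100), 12.5),
                OccupancySegment(GenomicInterval("chr1", 200, 250), 0.72)]
        p = tmp_path / "occ.bedgraph"
        write_bedgraph(p, segs)
        assert read_bedgraph(p) == segs

    def test_gtf_one_based_conversion(self, tmp_path):
        p = tmp_path / "g.gtf"
        p.write_text('chr1\tsrc\texon\t100\t120\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n')
        (gene,) = read_gene_models(p)
        assert gene.exons[0].start == 99 and gene.exons[0].end == 120

    def test_gtf_round_trip(self, tmp_path):
        genes = [make_gene("ga", strand="+"), make_gene("gb", strand="-",
                                                        exon_spans=((700, 800), (900, 1000)))]
        p = tmp_path / "rt.gtf"
        write_gtf(p, genes)
        back = read_gene_models(p)
        assert [(g.gene_id, g.exons) for g in back] == [(g.gene_id, g.exons) for g in genes]

    def test_bed12_blocks(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t100\t600\tgx\t0\t-\t100\t600\t0\t2\t50,60\t0,440\n")
        (gene,) = read_gene_models(p)
        assert gene.exons == (GenomicInterval("chr1", 100, 150, "-"),
                              GenomicInterval("chr1", 540, 600, "-"))
        assert gene.five_prime_exon.start == 540
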