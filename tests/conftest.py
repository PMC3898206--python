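import numpy as np
import pytest

from endosirna import GeneModel, GenomicInterval


def make_gene(gene_id="g", chrom="chr1", strand="+", exon_spans=((100, 200), (300, 400), (500, 600))):
    exons = tuple(GenomicInterval(chrom, s, e, strand) for s, e in exon_spans)
    body = GenomicInterval(chrom, exons[0].start, exons[-1].end, strand)
    return GeneModel(gene_id, body, exons)


@pytest.fixture
def three_exon_plus():
    return make_gene("gp", strand="+")


@pytest.fixture
def three_exon_minus():
    return make_gene("gm", strand="-")


@pytest.fixture
def single_exon_gene():
    return make_gene("gs", exon_spans=((100, 250),))


def random_intervals(rng, n, chrom_len=10_000, chroms=("chrA",), max_len=200, stranded=True):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, chrom_len - max_len))
        length = int(rng.integers(1, max_len))
        strand = rng.choice(["+", "-", "."]) if stranded else "."
        out.append(GenomicInterval(str(rng.choice(chroms)), start, start + length, strand))
    return out


def brute_force_intersect(a, b, strand_mode="ignore", min_overlap_bp=1):
    """Independent all-pairs oracle for the intersection engine."""
    records = []
    skipped = 0
    for i, x in enumerate(a):
        for j, y in enumerate(b):
            if x.chrom != y.chrom:
                continue
            ovl = min(x.end, y.end) - max(x.start, y.start)
            if ovl < min_overlap_bp:
                continue
            if strand_mode != "ignore":
                if x.strand == "." or y.strand == ".":
                    skipped += 1
                    continue
                if strand_mode == "same" and x.strand != y.strand:
                    continue
                if strand_mode == "opposite" and x.strand == y.strand:
                    continue
            records.append((i, j, ovl))
    return records, skipped
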