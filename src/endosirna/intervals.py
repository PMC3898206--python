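"""Coordinate conventions, interval arithmetic and the strand-aware
intersection engine.

All coordinates are 0-based, half-open (BED convention). GTF input, which is
1-based inclusive, is converted at the file boundary and never leaks into the
in-memory model. Strand is one of ``"+"``, ``"-"`` or ``"."`` (unstranded).
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

PLUS = "+"
MINUS = "-"
UNSTRANDED = "."
_STRANDS = (PLUS, MINUS, UNSTRANDED)


class ParseError(ValueError):
    """Malformed line in a BED/bedGraph/GTF file; carries the line number."""

    def __init__(self, path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


class ClassificationError(ValueError):
    """A read could not be assigned to an exon bin (no exonic overlap)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on ``chrom`` with a strand."""

    chrom: str
    start: int
    end: int
    strand: str = UNSTRANDED

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def stranded(self) -> bool:
        return self.strand != UNSTRANDED

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Shared bases with ``other``; 0 for different chromosomes or
        abutting half-open spans."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def shift(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset, self.strand)


@dataclass(frozen=True)
class OccupancySegment:
    """A bedGraph segment: an unstranded span carrying a non-negative signal
    value ("integrated units")."""

    span: GenomicInterval
    units: float

    def __post_init__(self):
        if self.units < 0:
            raise ValueError(f"units must be >= 0, got {self.units}")


class ExonBin(Enum):
    """Position of a read within its gene's exon structure, mapped through
    the gene strand (FIRST_5P is the transcriptionally first exon)."""

    FIRST_5P = "first_5p"
    INTERNAL = "internal"
    LAST_3P = "last_3p"
    SINGLE_EXON = "single_exon"
    OTHER = "other"


@dataclass(frozen=True)
class GeneModel:
    """Strand-aware exon structure of a gene.

    ``exons`` are in genomic order (sorted by start, non-overlapping, inside
    ``body``); the transcriptionally first exon is the genomically first for
    plus-strand genes and the genomically last for minus-strand genes.
    """

    gene_id: str
    body: GenomicInterval
    exons: tuple

    def __post_init__(self):
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.body.strand not in (PLUS, MINUS):
            raise ValueError(f"gene {self.gene_id}: body must be stranded")
        exons = tuple(self.exons)
        object.__setattr__(self, "exons", exons)
        if not exons:
            raise ValueError(f"gene {self.gene_id}: needs at least one exon")
        prev_end = None
        for e in exons:
            if e.chrom != self.body.chrom:
                raise ValueError(f"gene {self.gene_id}: exon on wrong chromosome")
            if e.start < self.body.start or e.end > self.body.end:
                raise ValueError(f"gene {self.gene_id}: exon outside body")
            if prev_end is not None and e.start < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or are unsorted")
            prev_end = e.end

    @property
    def strand(self) -> str:
        return self.body.strand

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def first_exon_start(self) -> int:
        """Genomic start of the genomically first exon (neighbor-distance anchor)."""
        return self.exons[0].start

    @property
    def last_exon_end(self) -> int:
        """Genomic end of the genomically last exon (neighbor-distance anchor)."""
        return self.exons[-1].end

    @property
    def five_prime_exon(self) -> GenomicInterval:
        return self.exons[0] if self.strand == PLUS else self.exons[-1]

    @property
    def three_prime_exon(self) -> GenomicInterval:
        return self.exons[-1] if self.strand == PLUS else self.exons[0]

    def exon_bin_of(self, exon_index: int) -> ExonBin:
        """Bin label of the exon at genomic index ``exon_index``."""
        n = self.n_exons
        if n == 1:
            return ExonBin.SINGLE_EXON
        if self.strand == PLUS:
            first, last = 0, n - 1
        else:
            first, last = n - 1, 0
        if exon_index == first:
            return ExonBin.FIRST_5P
        if exon_index == last:
            return ExonBin.LAST_3P
        return ExonBin.INTERNAL


# ---------------------------------------------------------------------------
# Intersection engine
# ---------------------------------------------------------------------------

STRAND_MODES = ("ignore", "same", "opposite")


@dataclass(frozen=True)
class OverlapRecord:
    a_index: int
    b_index: int
    overlap_bp: int


@dataclass
class IntersectResult:
    """Overlap pairs plus a diagnostics tally of pairs skipped because a
    strand-aware mode met an unstranded member."""

    records: list = field(default_factory=list)
    skipped_unstranded: int = 0

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


def _strand_ok(mode: str, sa: str, sb: str):
    """(passes, skipped) under the given strand mode."""
    if mode == "ignore":
        return True, False
    if sa == UNSTRANDED or sb == UNSTRANDED:
        return False, True
    if mode == "same":
        return sa == sb, False
    return sa != sb, False


def intersect(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    strand_mode: str = "ignore",
    min_overlap_bp: int = 1,
) -> IntersectResult:
    """Report every pair (i, j) with ``a[i]`` and ``b[j]`` sharing at least
    ``min_overlap_bp`` bases under ``strand_mode``.

    Output is sorted by a-index then b-index. Under ``same``/``opposite``
    modes a candidate pair with an unstranded member is skipped and counted
    in ``skipped_unstranded``.
    """
    if strand_mode not in STRAND_MODES:
        raise ValueError(f"strand_mode must be one of {STRAND_MODES}, got {strand_mode!r}")
    if not isinstance(min_overlap_bp, int) or min_overlap_bp < 1:
        raise ValueError(f"min_overlap_bp must be a positive integer, got {min_overlap_bp!r}")

    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for j, iv in enumerate(b):
        trees[iv.chrom].addi(iv.start, iv.end, j)

    result = IntersectResult()
    for i, iv in enumerate(a):
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        hits = []
        for node in tree.overlap(iv.start, iv.end):
            j = node.data
            ovl = min(iv.end, node.end) - max(iv.start, node.begin)
            if ovl < min_overlap_bp:
                continue
            ok, skipped = _strand_ok(strand_mode, iv.strand, b[j].strand)
            if skipped:
                result.skipped_unstranded += 1
            elif ok:
                hits.append(OverlapRecord(i, j, ovl))
        hits.sort(key=lambda r: r.b_index)
        result.records.extend(hits)
    return result


def classify_exon_bin(read: GenomicInterval, gene: GeneModel) -> ExonBin:
    """Assign a read to an exon bin of ``gene``: SINGLE_EXON for one-exon
    genes, otherwise the bin of the exon with maximal overlap; an exact
    overlap tie between exons of different bins yields OTHER."""
    overlaps = [read.overlap_bp(e) for e in gene.exons]
    best = max(overlaps)
    if best == 0:
        raise ClassificationError(
            f"read {read.chrom}:{read.start}-{read.end} overlaps no exon of {gene.gene_id}"
        )
    if gene.n_exons == 1:
        return ExonBin.SINGLE_EXON
    bins = {gene.exon_bin_of(i) for i, o in enumerate(overlaps) if o == best}
    return bins.pop() if len(bins) == 1 else ExonBin.OTHER


# ---------------------------------------------------------------------------
# File I/O (BED6 / bedGraph / GTF / BED12)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BedRecord:
    """One BED6 line: an interval plus name, score, and a read multiplicity
    (taken from the score column when the file stores collapsed reads)."""

    interval: GenomicInterval
    name: str = "."
    score: float = 0.0
    multiplicity: int = 1


def _data_lines(path):
    """Yield (lineno, fields) skipping blanks, '#' comments and track lines."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith(("track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_bed(path, score_is_multiplicity: bool = False) -> list:
    """Read a BED3/BED6 file into :class:`BedRecord` objects.

    With ``score_is_multiplicity`` the score column is interpreted as the
    collapsed-read multiplicity (must be a positive integer).
    """
    records = []
    for lineno, f in _data_lines(path):
        if len(f) < 3:
            raise ParseError(path, lineno, f"expected >=3 BED columns, got {len(f)}")
        try:
            iv = GenomicInterval(
                f[0], int(f[1]), int(f[2]), f[5] if len(f) >= 6 else UNSTRANDED
            )
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from exc
        name = f[3] if len(f) >= 4 else "."
        try:
            score = float(f[4]) if len(f) >= 5 and f[4] != "." else 0.0
        except ValueError as exc:
            raise ParseError(path, lineno, f"bad score {f[4]!r}") from exc
        mult = 1
        if score_is_multiplicity:
            mult = int(score)
            if mult < 1 or mult != score:
                raise ParseError(path, lineno, f"multiplicity must be a positive integer, got {f[4]}")
        records.append(BedRecord(iv, name, score, mult))
    return records


def write_bed(path, records: Iterable) -> None:
    """Write BED6. Accepts :class:`BedRecord` or bare :class:`GenomicInterval`."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, GenomicInterval):
                rec = BedRecord(rec)
            iv = rec.interval
            score = rec.score
            if score == int(score):
                score = int(score)
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rec.name}\t{score}\t{iv.strand}\n")


def read_bedgraph(path) -> list:
    """Read a 4-column bedGraph into :class:`OccupancySegment` objects."""
    segments = []
    for lineno, f in _data_lines(path):
        if len(f) < 4:
            raise ParseError(path, lineno, f"expected 4 bedGraph columns, got {len(f)}")
        try:
            segments.append(
                OccupancySegment(GenomicInterval(f[0], int(f[1]), int(f[2])), float(f[3]))
            )
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from exc
    return segments


def write_bedgraph(path, segments: Iterable[OccupancySegment]) -> None:
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(f"{seg.span.chrom}\t{seg.span.start}\t{seg.span.end}\t{seg.units:g}\n")


def _merge_intervals(ivs: list) -> list:
    """Union-merge possibly overlapping exon spans (same chrom/strand)."""
    ivs = sorted(ivs, key=lambda iv: (iv.start, iv.end))
    merged = [ivs[0]]
    for iv in ivs[1:]:
        last = merged[-1]
        if iv.start <= last.end:
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end, last.strand)
        else:
            merged.append(iv)
    return merged


def _genes_from_exons(exons_by_gene: dict) -> list:
    genes = []
    for gene_id, (chrom, strand, spans) in exons_by_gene.items():
        merged = tuple(_merge_intervals(spans))
        body = GenomicInterval(chrom, merged[0].start, merged[-1].end, strand)
        genes.append(GeneModel(gene_id, body, merged))
    genes.sort(key=lambda g: (g.body.chrom, g.body.start, g.gene_id))
    return genes


def read_gene_models(path) -> list:
    """Read gene models from GTF/GFF (via gffutils) or BED12.

    GTF 1-based inclusive coordinates become internal 0-based half-open.
    Exons of all transcripts of a gene are union-merged so the model meets
    the non-overlapping invariant.
    """
    path = Path(path)
    if path.suffix.lower() in (".bed", ".bed12"):
        return _read_bed12(path)
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises heterogeneous errors
        raise ParseError(path, 0, f"GTF/GFF parse failure: {exc}") from exc
    exons_by_gene: dict = {}
    for feat in db.features_of_type("exon"):
        gene_ids = feat.attributes.get("gene_id") or feat.attributes.get("Parent")
        if not gene_ids:
            raise ParseError(path, 0, f"exon at {feat.seqid}:{feat.start} lacks gene_id")
        gid = gene_ids[0]
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        entry = exons_by_gene.setdefault(gid, (feat.seqid, feat.strand, []))
        if entry[0] != feat.seqid or entry[1] != feat.strand:
            raise ParseError(path, 0, f"gene {gid}: exons on multiple chromosomes/strands")
        entry[2].append(iv)
    if not exons_by_gene:
        warnings.warn(f"{path}: no exon features found", stacklevel=2)
    return _genes_from_exons(exons_by_gene)


def _read_bed12(path) -> list:
    exons_by_gene: dict = {}
    for lineno, f in _data_lines(path):
        if len(f) < 12:
            raise ParseError(path, lineno, f"expected 12 BED12 columns, got {len(f)}")
        try:
            chrom, start, strand, name = f[0], int(f[1]), f[5], f[3]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != int(f[9]) or len(starts) != int(f[9]):
                raise ValueError("blockCount disagrees with block lists")
            spans = [
                GenomicInterval(chrom, start + off, start + off + size, strand)
                for off, size in zip(starts, sizes)
            ]
        except ValueError as exc:
            raise ParseError(path, lineno, str(exc)) from exc
        entry = exons_by_gene.setdefault(name, (chrom, strand, []))
        if entry[0] != chrom or entry[1] != strand:
            raise ParseError(path, lineno, f"gene {name}: records on multiple chromosomes/strands")
        entry[2].extend(spans)
    return _genes_from_exons(exons_by_gene)


def write_gtf(path, genes: Iterable[GeneModel], source: str = "endosirna") -> None:
    """Write gene models as GTF exon lines (internal 0-based half-open spans
    become 1-based inclusive on output)."""
    with open(path, "w") as fh:
        for g in genes:
            for e in g.exons:
                attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
                fh.write(
                    f"{e.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )
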