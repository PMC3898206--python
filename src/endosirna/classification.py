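"""Sorting aligned short reads into RNA classes, the 16-30 nt length filter,
read collapsing, per-gene orientation statistics and outlier-gene exclusion.

Reads are classified with the priority miRNA > structural RNA > genic
(exonic) > other-genic (intragenic but intron-only) > nongenic, so each read
lands in exactly one class. "Genic" reads surviving the length filter are the
operational endo-siRNA candidates everything downstream consumes.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .intervals import (
    ExonBin,
    GeneModel,
    GenomicInterval,
    UNSTRANDED,
    classify_exon_bin,
    intersect,
)

MIN_READ_LEN = 16
MAX_READ_LEN = 30

READ_CLASSES = ("mirna", "structural", "genic", "other_genic", "nongenic")


@dataclass(frozen=True)
class CollapsedRead:
    """A unique alignment span with the number of identical raw reads."""

    span: GenomicInterval
    multiplicity: int = 1

    def __post_init__(self):
        if self.multiplicity < 1:
            raise ValueError(f"multiplicity must be >= 1, got {self.multiplicity}")

    @property
    def length(self) -> int:
        return self.span.length


def _span(read) -> GenomicInterval:
    return read.span if isinstance(read, CollapsedRead) else read


def _mult(read) -> int:
    return read.multiplicity if isinstance(read, CollapsedRead) else 1


@dataclass
class ReadClassBreakdown:
    """Per-class read counts and fractions of the total input (Fig-1A-style
    pie breakdown); ``reads`` holds the per-class read lists."""

    counts: dict
    fractions: dict
    total: int
    reads: dict = field(repr=False, default_factory=dict)


def categorize_reads(
    reads: Sequence,
    mirna_annot: Sequence[GenomicInterval],
    structural_annot: Sequence[GenomicInterval],
    gene_models: Sequence[GeneModel],
) -> ReadClassBreakdown:
    """Assign every read to exactly one class by annotation priority
    miRNA > structural > genic (exon overlap) > other-genic (gene body
    only) > nongenic. Overlap is strand-ignored, minimum 1 bp.

    Empty annotation sets are allowed. A chromosome present in the reads but
    in no annotation triggers a warning with per-chromosome tallies.
    """
    spans = [_span(r) for r in reads]
    mults = [_mult(r) for r in reads]

    exon_ivs = [e for g in gene_models for e in g.exons]
    body_ivs = [g.body for g in gene_models]

    assigned = np.full(len(reads), -1)  # index into READ_CLASSES
    layers = [list(mirna_annot), list(structural_annot), exon_ivs, body_ivs]
    for level, annot in enumerate(layers):
        if not annot:
            continue
        for rec in intersect(spans, annot, strand_mode="ignore"):
            if assigned[rec.a_index] < 0:
                assigned[rec.a_index] = level
    assigned[assigned < 0] = 4  # nongenic

    counts = {c: 0 for c in READ_CLASSES}
    by_class: dict = {c: [] for c in READ_CLASSES}
    for read, mult, level in zip(reads, mults, assigned):
        cls = READ_CLASSES[level]
        counts[cls] += mult
        by_class[cls].append(read)

    annot_chroms = {iv.chrom for layer in layers for iv in layer}
    missing = Counter(s.chrom for s in spans if s.chrom not in annot_chroms)
    if missing and annot_chroms:
        warnings.warn(
            f"reads on chromosomes absent from every annotation: {dict(missing)}",
            stacklevel=2,
        )

    total = sum(mults)
    return ReadClassBreakdown(
        counts=counts, fractions=class_fractions(counts, total), total=total, reads=by_class
    )


def class_fractions(counts: Mapping[str, int], total: int) -> dict:
    """Per-class fraction of the total read population (the derived column
    of the class-breakdown table)."""
    if total < 0:
        raise ValueError("total must be >= 0")
    return {c: (n / total if total else 0.0) for c, n in counts.items()}


def length_filter(reads: Iterable, min_len: int = MIN_READ_LEN, max_len: int = MAX_READ_LEN) -> list:
    """Keep reads with ``min_len <= length <= max_len`` (both inclusive)."""
    if min_len > max_len:
        raise ValueError(f"min_len ({min_len}) must not exceed max_len ({max_len})")
    out = []
    for r in reads:
        length = _span(r).length
        if min_len <= length <= max_len:
            out.append(r)
    return out


def collapse_reads(reads: Iterable) -> list:
    """Merge reads identical in (chrom, start, end, strand) into
    :class:`CollapsedRead` records; total multiplicity is conserved and
    strand is part of read identity. Output is coordinate-sorted."""
    tally: Counter = Counter()
    for r in reads:
        tally[_span(r)] += _mult(r)
    return [
        CollapsedRead(span, mult)
        for span, mult in sorted(tally.items(), key=lambda kv: kv[0])
    ]


def assign_reads_to_genes(reads: Sequence, gene_models: Sequence[GeneModel]):
    """Assign each read to the gene whose exons it overlaps most.

    Returns ``(assignments, ambiguous)`` where ``assignments`` is a list of
    ``(read, gene_id)`` and ``ambiguous`` the reads tied between genes (the
    tie is logged as a returned tally, not silently dropped).
    """
    exon_owner = []
    exon_ivs = []
    for g in gene_models:
        for e in g.exons:
            exon_owner.append(g.gene_id)
            exon_ivs.append(e)
    spans = [_span(r) for r in reads]
    per_read: list = [defaultdict(int) for _ in reads]
    for rec in intersect(spans, exon_ivs, strand_mode="ignore"):
        per_read[rec.a_index][exon_owner[rec.b_index]] += rec.overlap_bp
    assignments, ambiguous = [], []
    for read, gene_ovl in zip(reads, per_read):
        if not gene_ovl:
            continue
        best = max(gene_ovl.values())
        winners = [gid for gid, o in gene_ovl.items() if o == best]
        if len(winners) == 1:
            assignments.append((read, winners[0]))
        else:
            ambiguous.append(read)
    return assignments, ambiguous


def bin_reads_by_exon(assigned_reads: Sequence, gene_models) -> dict:
    """Group gene-assigned reads by exon bin (see
    :func:`~endosirna.intervals.classify_exon_bin`); returns a dict with an
    entry for every :class:`ExonBin` member."""
    if not isinstance(gene_models, Mapping):
        gene_models = {g.gene_id: g for g in gene_models}
    binned: dict = {b: [] for b in ExonBin}
    for read, gid in assigned_reads:
        binned[classify_exon_bin(_span(read), gene_models[gid])].append(read)
    return binned


@dataclass(frozen=True)
class GeneOrientationRecord:
    gene_id: str
    sense_reads: int
    antisense_reads: int
    bidirectional_flag: bool


@dataclass
class OrientationSummary:
    records: list
    sense_fraction: float
    n_unstranded_excluded: int


def orientation_summary(
    assigned_reads: Sequence,
    gene_models: Mapping[str, GeneModel] | Sequence[GeneModel],
    threshold: int = 5,
) -> OrientationSummary:
    """Per-gene sense/antisense read counts and the global sense fraction.

    ``assigned_reads`` is a sequence of ``(read, gene_id)`` pairs (see
    :func:`assign_reads_to_genes`). A gene is flagged bidirectional iff both
    its sense and antisense counts strictly exceed ``threshold``. Unstranded
    reads are excluded and tallied. Counts are multiplicity-weighted.
    """
    if not isinstance(gene_models, Mapping):
        gene_models = {g.gene_id: g for g in gene_models}
    sense: Counter = Counter()
    anti: Counter = Counter()
    n_unstranded = 0
    for read, gid in assigned_reads:
        span = _span(read)
        if span.strand == UNSTRANDED:
            n_unstranded += 1
            continue
        if span.strand == gene_models[gid].strand:
            sense[gid] += _mult(read)
        else:
            anti[gid] += _mult(read)
    records = [
        GeneOrientationRecord(
            gid,
            sense[gid],
            anti[gid],
            sense[gid] > threshold and anti[gid] > threshold,
        )
        for gid in sorted(set(sense) | set(anti))
    ]
    total_sense = sum(sense.values())
    total = total_sense + sum(anti.values())
    fraction = total_sense / total if total else float("nan")
    return OrientationSummary(records, fraction, n_unstranded)


def flag_outlier_genes(
    per_gene_counts: Mapping[str, int],
    max_fraction: float = 0.5,
    explicit: Optional[Iterable[str]] = None,
) -> set:
    """Genes whose reads dominate the dataset and should be excluded from
    quantitative summaries.

    An explicit exclusion list wins outright. Otherwise the smallest set of
    top genes (by count) whose cumulative share exceeds ``max_fraction`` is
    flagged; if only the entire gene set exceeds it, no gene is
    disproportionate and nothing is flagged.
    """
    if explicit is not None:
        return set(explicit)
    if not (0 < max_fraction <= 1):
        raise ValueError(f"max_fraction must be in (0, 1], got {max_fraction}")
    total = sum(per_gene_counts.values())
    if total <= 0:
        return set()
    ranked = sorted(per_gene_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    cum = 0
    for k, (gid, count) in enumerate(ranked, start=1):
        cum += count
        if cum / total > max_fraction:
            if k == len(ranked):
                return set()
            return {g for g, _ in ranked[:k]}
    return set()


@dataclass
class LengthProfile:
    """Histogram of read lengths over 16..30 nt (15 bins).

    Expanded mode weights each collapsed read by its multiplicity; collapsed
    mode counts each unique alignment once.
    """

    counts: np.ndarray
    min_len: int = MIN_READ_LEN
    max_len: int = MAX_READ_LEN

    @property
    def lengths(self) -> np.ndarray:
        return np.arange(self.min_len, self.max_len + 1)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def peak_length(self) -> int:
        """Length of the most populated bin (ties -> shortest)."""
        return int(self.lengths[int(np.argmax(self.counts))])

    def __add__(self, other: "LengthProfile") -> "LengthProfile":
        if (self.min_len, self.max_len) != (other.min_len, other.max_len):
            raise ValueError("profiles cover different length ranges")
        return LengthProfile(self.counts + other.counts, self.min_len, self.max_len)


def length_profile(
    reads: Iterable,
    collapsed: bool = False,
    min_len: int = MIN_READ_LEN,
    max_len: int = MAX_READ_LEN,
) -> LengthProfile:
    """Exact length histogram; input must already be length-filtered."""
    counts = np.zeros(max_len - min_len + 1, dtype=np.int64)
    for r in reads:
        length = _span(r).length
        if not (min_len <= length <= max_len):
            raise ValueError(
                f"read length {length} outside [{min_len}, {max_len}]; apply length_filter first"
            )
        counts[length - min_len] += 1 if collapsed else _mult(r)
    return LengthProfile(counts, min_len, max_len)
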