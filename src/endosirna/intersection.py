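"""Per-exon-bin intersection statistics of collapsed endo-siRNA reads with
an occupancy signal track (RNAPII-ChIP-style bedGraph) and with a CLASH
interval set (AGO-bound reads), plus stringency filtering and per-subset
length profiles.

Occupancy intersection is strand-ignored (ChIP signal is unstranded); CLASH
intersection is strand-ignored by default with a same-strand option. A
read's "integrated units" are, under the default ``prorated`` rule, the sum
over touched segments of ``units * overlap_bp / segment_length``; the
``full`` rule sums the whole units value of every touched segment.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import ExonBin, GenomicInterval, OccupancySegment, intersect
from .classification import LengthProfile, length_profile, _span

UNIT_RULES = ("prorated", "full")

# report row order: total first, then 5', 3', internal, single-exon, other
BIN_ORDER = (
    ExonBin.FIRST_5P,
    ExonBin.LAST_3P,
    ExonBin.INTERNAL,
    ExonBin.SINGLE_EXON,
    ExonBin.OTHER,
)
BIN_LABELS = {
    ExonBin.FIRST_5P: "5'",
    ExonBin.LAST_3P: "3'",
    ExonBin.INTERNAL: "Internal exons",
    ExonBin.SINGLE_EXON: "1 exon genes",
    ExonBin.OTHER: "Others",
}
TOTAL_LABEL = "Total reads"


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half-away-from-zero to ``ndigits`` decimals (report convention;
    Python's built-in ``round`` is banker's rounding and prints 129.55 as
    129.5 where the reports need 129.6)."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return float("nan")
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def round1(x: float) -> float:
    """Round half-away-from-zero to one decimal."""
    return round_half_away(x, 1)


@dataclass
class BinSummary:
    """One row of the occupancy panel: reads in the bin, how many touch the
    signal track, and the summed/average integrated units."""

    bin_label: str
    total_reads: int
    overlapping_reads: int
    total_units: float
    empty_bin: bool = False

    @property
    def percent_overlap(self) -> float:
        if self.total_reads == 0:
            return 0.0
        return 100.0 * self.overlapping_reads / self.total_reads

    @property
    def average_units(self) -> float:
        if self.total_reads == 0:
            return 0.0
        return self.total_units / self.total_reads


@dataclass
class ClashBinSummary:
    """One row of the CLASH panel: distinct CLASH records touching the bin's
    siRNA reads, siRNA reads with at least one CLASH overlap, and their
    ratio (NA when nothing intersects)."""

    bin_label: str
    clash_reads: int
    intersected_sirna_reads: int
    total_sirna_reads: int

    @property
    def ratio(self) -> Optional[float]:
        if self.intersected_sirna_reads == 0:
            return None
        return self.clash_reads / self.intersected_sirna_reads

    @property
    def percent(self) -> float:
        if self.total_sirna_reads == 0:
            return 0.0
        return 100.0 * self.intersected_sirna_reads / self.total_sirna_reads


def assign_read_units(
    reads: Sequence,
    occupancy: Sequence[OccupancySegment],
    rule: str = "prorated",
    min_overlap_bp: int = 1,
) -> np.ndarray:
    """Integrated units attributed to each read (strand-ignored)."""
    if rule not in UNIT_RULES:
        raise ValueError(f"rule must be one of {UNIT_RULES}, got {rule!r}")
    spans = [_span(r) for r in reads]
    seg_spans = [seg.span for seg in occupancy]
    units = np.zeros(len(reads))
    for rec in intersect(spans, seg_spans, strand_mode="ignore", min_overlap_bp=min_overlap_bp):
        seg = occupancy[rec.b_index]
        if rule == "prorated":
            units[rec.a_index] += seg.units * rec.overlap_bp / seg.span.length
        else:
            units[rec.a_index] += seg.units
    return units


def _merged_union(spans):
    """Per-chromosome merged interval union as sorted (starts, ends) arrays."""
    by_chrom: dict = defaultdict(list)
    for iv in spans:
        by_chrom[iv.chrom].append((iv.start, iv.end))
    unions = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        starts, ends = [], []
        for s, e in pairs:
            if ends and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        unions[chrom] = (np.array(starts), np.array(ends))
    return unions


def _hits_union(span, unions) -> bool:
    entry = unions.get(span.chrom)
    if entry is None:
        return False
    starts, ends = entry
    i = int(np.searchsorted(ends, span.start, side="right"))
    return i < len(starts) and starts[i] < span.end


def _overlap_mask(reads, partner_spans, strand_mode="ignore", min_overlap_bp=1):
    """Boolean mask: which reads share >= min_overlap_bp bases with any
    partner interval. For the 1 bp default this runs on merged unions
    (O(n log n)) instead of enumerating pairs."""
    spans = [_span(r) for r in reads]
    if min_overlap_bp == 1:
        if strand_mode == "ignore":
            unions = _merged_union(partner_spans)
            return np.array([_hits_union(s, unions) for s in spans], dtype=bool)
        by_strand = {
            st: _merged_union([p for p in partner_spans if p.strand == st])
            for st in ("+", "-")
        }
        flip = {"+": "-", "-": "+"}
        mask = np.zeros(len(spans), dtype=bool)
        for i, s in enumerate(spans):
            if s.strand == ".":
                continue
            target = s.strand if strand_mode == "same" else flip[s.strand]
            mask[i] = _hits_union(s, by_strand[target])
        return mask
    mask = np.zeros(len(reads), dtype=bool)
    for rec in intersect(spans, partner_spans, strand_mode=strand_mode, min_overlap_bp=min_overlap_bp):
        mask[rec.a_index] = True
    return mask


def summarize_occupancy(
    binned_reads: Mapping[ExonBin, Sequence],
    occupancy: Sequence[OccupancySegment],
    rule: str = "prorated",
    min_overlap_bp: int = 1,
) -> list:
    """Occupancy panel: one :class:`BinSummary` per exon bin plus a TOTAL
    row recomputed over all reads. A read overlaps if it shares at least
    ``min_overlap_bp`` bases with any segment.

    Empty bins are emitted with zero counts and ``empty_bin`` set, so the
    report shape is stable regardless of the data.
    """
    seg_spans = [seg.span for seg in occupancy]
    rows = []
    all_reads: list = []
    for b in BIN_ORDER:
        reads = list(binned_reads.get(b, ()))
        all_reads.extend(reads)
        if not reads:
            rows.append(BinSummary(BIN_LABELS[b], 0, 0, 0.0, empty_bin=True))
            continue
        units = assign_read_units(reads, occupancy, rule=rule, min_overlap_bp=min_overlap_bp)
        mask = _overlap_mask(reads, seg_spans, min_overlap_bp=min_overlap_bp)
        rows.append(
            BinSummary(BIN_LABELS[b], len(reads), int(mask.sum()), float(units.sum()))
        )
    if all_reads:
        units = assign_read_units(all_reads, occupancy, rule=rule, min_overlap_bp=min_overlap_bp)
        mask = _overlap_mask(all_reads, seg_spans, min_overlap_bp=min_overlap_bp)
        total_row = BinSummary(TOTAL_LABEL, len(all_reads), int(mask.sum()), float(units.sum()))
    else:
        total_row = BinSummary(TOTAL_LABEL, 0, 0, 0.0, empty_bin=True)
    return [total_row] + rows


def stringency_filter(
    reads: Sequence,
    occupancy: Sequence[OccupancySegment],
    mode: str,
    value: float,
    rule: str = "prorated",
) -> list:
    """Keep reads mapping to highly occupied regions.

    ``units_threshold`` keeps reads whose assigned units are >= ``value``
    (the boundary read is kept). ``percentile`` derives the units cutoff as
    that percentile of the per-read units distribution, then applies the
    same >= rule.
    """
    if mode not in ("units_threshold", "percentile"):
        raise ValueError(f"mode must be 'units_threshold' or 'percentile', got {mode!r}")
    if mode == "units_threshold" and value < 0:
        raise ValueError(f"units threshold must be >= 0, got {value}")
    if mode == "percentile" and not (0 <= value <= 100):
        raise ValueError(f"percentile must be in [0, 100], got {value}")
    reads = list(reads)
    units = assign_read_units(reads, occupancy, rule=rule)
    cutoff = value if mode == "units_threshold" else float(np.percentile(units, value)) if reads else 0.0
    return [r for r, u in zip(reads, units) if u >= cutoff]


def summarize_clash(
    binned_reads: Mapping[ExonBin, Sequence],
    clash_reads: Sequence[GenomicInterval],
    strand_mode: str = "ignore",
    min_overlap_bp: int = 1,
) -> list:
    """CLASH panel: per exon bin, how many siRNA reads intersect at least
    one CLASH record and how many distinct CLASH records touch the bin.

    A CLASH record overlapping several siRNA reads of one bin is counted
    once for that bin (so the per-bin CLASH tallies never exceed the CLASH
    library size); the TOTAL row is recomputed over all reads at once.
    """
    clash_spans = list(clash_reads)

    def _row(label, reads):
        if not reads:
            return ClashBinSummary(label, 0, 0, 0)
        spans = [_span(r) for r in reads]
        # symmetric masks avoid materializing the full overlap pair list
        sirna_hit = _overlap_mask(reads, clash_spans, strand_mode, min_overlap_bp)
        clash_hit = _overlap_mask(clash_spans, spans, strand_mode, min_overlap_bp)
        return ClashBinSummary(label, int(clash_hit.sum()), int(sirna_hit.sum()), len(reads))

    rows = []
    all_reads: list = []
    for b in BIN_ORDER:
        reads = list(binned_reads.get(b, ()))
        all_reads.extend(reads)
        rows.append(_row(BIN_LABELS[b], reads))
    return [_row(TOTAL_LABEL, all_reads)] + rows


def profile_by_overlap(
    reads: Sequence,
    partner_set: Sequence[GenomicInterval],
    strand_mode: str = "ignore",
    min_overlap_bp: int = 1,
    collapsed: bool = False,
):
    """Split reads by whether they overlap the partner set and return the
    pair of length profiles (overlapping, non-overlapping); the two
    partition the total profile bin-wise."""
    reads = list(reads)
    mask = _overlap_mask(reads, list(partner_set), strand_mode=strand_mode, min_overlap_bp=min_overlap_bp)
    hit = [r for r, m in zip(reads, mask) if m]
    miss = [r for r, m in zip(reads, mask) if not m]
    return length_profile(hit, collapsed=collapsed), length_profile(miss, collapsed=collapsed)


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------


def occupancy_table(summaries: Iterable[BinSummary]) -> pd.DataFrame:
    """Occupancy panel as a table, percents/averages rounded to 1 decimal."""
    return pd.DataFrame(
        {
            "bin": s.bin_label,
            "integrated_units": round1(s.total_units),
            "total_sirna_reads": s.total_reads,
            "average_units": round1(s.average_units),
            "reads_with_occupancy": s.overlapping_reads,
            "percent": round1(s.percent_overlap),
        }
        for s in summaries
    )


def clash_table(summaries: Iterable[ClashBinSummary]) -> pd.DataFrame:
    """CLASH panel as a table; undefined ratios render as NA."""
    return pd.DataFrame(
        {
            "bin": s.bin_label,
            "clash_reads": s.clash_reads,
            "intersected_sirna_reads": s.intersected_sirna_reads,
            "clash_per_sirna": round1(s.ratio) if s.ratio is not None else float("nan"),
            "total_sirna_reads": s.total_sirna_reads,
            "percent": round1(s.percent),
        }
        for s in summaries
    )
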