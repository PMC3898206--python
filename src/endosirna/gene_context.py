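"""Neighbor-gene configuration and distance analysis, and natural-antisense
(NAT) category enrichment.

Adjacent gene pairs are classified by strand geometry: divergent 5'<->5'
(HEAD_TO_HEAD), tandem same-strand (TAIL_TO_HEAD) and convergent 3'<->3'
(TAIL_TO_TAIL) — only convergent pairs can support exonic sense/antisense
overlap. The inter-gene distance is the start coordinate of the following
gene's first exon minus the end coordinate of the preceding gene's last
exon; overlapping neighbors get a negative distance and are retained by
default.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GeneModel, MINUS, PLUS
from .intersection import round1

HEAD_TO_HEAD = "HEAD_TO_HEAD"
TAIL_TO_HEAD = "TAIL_TO_HEAD"
TAIL_TO_TAIL = "TAIL_TO_TAIL"
CONFIGURATIONS = (HEAD_TO_HEAD, TAIL_TO_HEAD, TAIL_TO_TAIL)

NAT_CATEGORIES = ("NBD", "NOB", "SA")
NAT_LABELS = {
    "NBD": "Non Bi-Directional (NBD)",
    "NOB": "Non Overlapping SA (NOB)",
    "SA": "Sense/Antisense (SA)",
}


@dataclass(frozen=True)
class GenePairRecord:
    """A gene and one of its immediate neighbors; configuration and distance
    are pair-level properties, identical from either member."""

    gene_id: str
    neighbor_id: str
    configuration: str
    distance: int
    focal_read_count: int = 0


def _pair_configuration(left: GeneModel, right: GeneModel) -> str:
    """Configuration of two genes given in genomic order."""
    if left.strand == right.strand:
        return TAIL_TO_HEAD
    if left.strand == PLUS and right.strand == MINUS:
        return TAIL_TO_TAIL  # both 3' ends face the gap
    return HEAD_TO_HEAD


def neighbor_pairs(
    genes: Sequence[GeneModel],
    read_counts: Optional[Mapping[str, int]] = None,
    keep_overlapping: bool = True,
) -> list:
    """For every gene, a record per immediately adjacent neighbor on the
    same chromosome (two records per adjacency, one from each member).

    Distance = start(first exon of the following gene) - end(last exon of
    the preceding gene); negative means the neighbors overlap (dropped if
    ``keep_overlapping`` is false). Chromosomes holding a single gene yield
    no pair.
    """
    read_counts = read_counts or {}
    by_chrom: dict = defaultdict(list)
    for g in genes:
        by_chrom[g.body.chrom].append(g)
    records = []
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda g: (g.first_exon_start, g.gene_id))
        for left, right in zip(ordered, ordered[1:]):
            distance = right.first_exon_start - left.last_exon_end
            if distance < 0 and not keep_overlapping:
                continue
            config = _pair_configuration(left, right)
            for focal, other in ((left, right), (right, left)):
                records.append(
                    GenePairRecord(
                        focal.gene_id,
                        other.gene_id,
                        config,
                        distance,
                        read_counts.get(focal.gene_id, 0),
                    )
                )
    return records


@dataclass
class FitResult:
    slope: float
    intercept: float
    r_squared: float
    n: int


def distance_readcount_fit(
    pairs: Sequence[GenePairRecord],
    configuration_filter: Optional[str] = None,
    max_distance: Optional[int] = None,
    log_counts: bool = False,
) -> FitResult:
    """Ordinary least squares of focal read count on neighbor distance.

    ``configuration_filter`` restricts to one pair configuration and
    ``max_distance`` to "near" neighbors (no default claimed: the choice of
    nearness is the caller's). ``log_counts`` fits log2(count + 1). A
    distance vector with zero variance leaves r_squared undefined (NaN).
    """
    if configuration_filter is not None and configuration_filter not in CONFIGURATIONS:
        raise ValueError(f"unknown configuration {configuration_filter!r}")
    sel = [
        p
        for p in pairs
        if (configuration_filter is None or p.configuration == configuration_filter)
        and (max_distance is None or p.distance <= max_distance)
    ]
    if len(sel) < 3:
        raise ValueError(f"need at least 3 pairs after filtering, got {len(sel)}")
    x = np.array([p.distance for p in sel], dtype=float)
    y = np.array([p.focal_read_count for p in sel], dtype=float)
    if log_counts:
        y = np.log2(y + 1.0)
    if np.ptp(x) == 0:
        return FitResult(float("nan"), float("nan"), float("nan"), len(sel))
    fit = stats.linregress(x, y)
    return FitResult(fit.slope, fit.intercept, fit.rvalue**2, len(sel))


@dataclass
class NatCategoryTable:
    """Counts and percentages of NAT categories (SA: sense/antisense
    overlapping, NOB: bidirectional non-overlapping, NBD: non-bidirectional)
    in a focal gene set versus the genome-wide background."""

    table: pd.DataFrame
    chi2: Optional[float] = None
    p_value: Optional[float] = None


def _category_counts(categories) -> dict:
    if isinstance(categories, Mapping) and not isinstance(categories, dict):
        categories = dict(categories)
    if isinstance(categories, dict) and set(categories) <= set(NAT_CATEGORIES):
        counts = {c: int(categories.get(c, 0)) for c in NAT_CATEGORIES}
    else:
        # mapping gene_id -> category, or a bare sequence of category labels
        labels = categories.values() if isinstance(categories, Mapping) else categories
        counts = {c: 0 for c in NAT_CATEGORIES}
        for lab in labels:
            if lab not in counts:
                raise ValueError(f"unknown NAT category {lab!r}")
            counts[lab] += 1
    return counts


def nat_enrichment(focal_categories, background_categories, test: bool = False) -> NatCategoryTable:
    """Category representation of the focal set versus the background, as
    counts and column percentages (rounded to 1 decimal in the table).

    Inputs may be per-category count dicts, gene_id -> category mappings, or
    sequences of labels. ``test`` adds a 3x2 chi-square statistic.
    """
    focal = _category_counts(focal_categories)
    background = _category_counts(background_categories)
    for name, counts in (("focal", focal), ("background", background)):
        if sum(counts.values()) == 0:
            raise ValueError(f"{name} category column is empty")
    f_total = sum(focal.values())
    b_total = sum(background.values())
    table = pd.DataFrame(
        {
            "category": [NAT_LABELS[c] for c in NAT_CATEGORIES],
            "focal_count": [focal[c] for c in NAT_CATEGORIES],
            "focal_percent": [round1(100.0 * focal[c] / f_total) for c in NAT_CATEGORIES],
            "background_count": [background[c] for c in NAT_CATEGORIES],
            "background_percent": [round1(100.0 * background[c] / b_total) for c in NAT_CATEGORIES],
        }
    )
    chi2 = p = None
    if test:
        observed = np.array(
            [[focal[c] for c in NAT_CATEGORIES], [background[c] for c in NAT_CATEGORIES]]
        )
        chi2, p, _, _ = stats.chi2_contingency(observed)
    return NatCategoryTable(table, chi2, p)


def read_nat_table(path) -> dict:
    """Two-column TSV (gene_id, category) -> mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "category"], comment="#")
    bad = set(df["category"]) - set(NAT_CATEGORIES)
    if bad:
        raise ValueError(f"unknown NAT categories in {path}: {sorted(bad)}")
    return dict(zip(df["gene_id"], df["category"]))
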