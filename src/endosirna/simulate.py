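"""Seeded generators for every input the pipeline consumes, with planted
statistical structure so each analysis stage has ground truth.

The generator emulates the study conditions this pipeline targets: a
16-30 nt genic read population with a broad peak around 22 nt, a ~70:30
sense:antisense orientation mix, read placement biased to first and last
exons, occupancy signal concentrated on 5' first exons, sparse CLASH
coverage coupled to a subset of the reads, and three-clone count tables
with a low-variance (miRNA-like), a high-variance down-biased
(snoRNA-like) and an intermediate (endo-siRNA-like) feature subset.

Genes are laid out on a single synthetic chromosome ("chrS") as disjoint
cassette pairs: the configured head-to-head / tail-to-head / tail-to-tail
arrangement mix is realized exactly (up to rounding) over the planted
pairs, whose identities land in the ground-truth manifest, and gaps between
cassettes are drawn much larger than intra-pair distances. (A linear gene
chain cannot make every adjacency convergent — convergent and divergent
adjacencies alternate by strand geometry — so the mix is planted on the
cassette pairs, not on every adjacency.)

All randomness flows from ``SimulationConfig.seed``; each generator uses
its own fixed substream, so outputs are reproducible individually and as a
bundle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    GeneModel,
    GenomicInterval,
    MINUS,
    OccupancySegment,
    PLUS,
    write_bed,
    write_bedgraph,
    write_gtf,
    BedRecord,
)
from .classification import MIN_READ_LEN, MAX_READ_LEN
from .gene_context import HEAD_TO_HEAD, TAIL_TO_HEAD, TAIL_TO_TAIL

_SUBSTREAM = {"annotation": 1, "reads": 2, "mixture": 3, "tracks": 4, "clones": 5}


def _rng(config, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), _SUBSTREAM[stage]])


@dataclass
class SimulationConfig:
    """Planted parameters of the synthetic study.

    Defaults mirror the conditions the pipeline is meant to recover: the
    69.4% sense fraction, the 22 nt length peak over 16-30 nt, exon-bin
    weights favoring first and last exons, 5'-biased occupancy and the
    three clone variance regimes.
    """

    seed: int = 0
    chrom: str = "chrS"
    chrom_length: Optional[int] = None  # None: auto-sized to fit the genes

    # gene layout
    n_genes: int = 200
    single_exon_gene_fraction: float = 0.106
    exon_count_mean: float = 4.0  # multi-exon genes: 2 + Poisson(mean - 2)
    exon_len_min: int = 80
    exon_len_mean: float = 200.0
    intron_len_mean: float = 400.0
    mean_intergenic_distance: float = 5000.0  # within a cassette pair
    inter_cassette_gap_factor: float = 10.0
    arrangement_mix: dict = field(
        default_factory=lambda: {HEAD_TO_HEAD: 1 / 3, TAIL_TO_HEAD: 1 / 3, TAIL_TO_TAIL: 1 / 3}
    )
    sa_overlap_fraction: float = 0.0  # fraction of TT pairs made to overlap

    # decoy annotations (placed in inter-cassette gaps)
    n_mirna: int = 30
    mirna_len: int = 80
    n_structural: int = 20
    structural_len: int = 130

    # genic read population
    n_reads: int = 10000
    length_peak: int = 22
    length_width: int = 4
    length_baseline: float = 0.02
    sense_fraction: float = 0.694
    exon_bin_weights: tuple = (0.253, 0.225, 0.378)  # first / internal / last
    abundance_sigma: float = 1.3  # log-normal per-gene abundance (heavy tail)

    # mixed population class fractions (of all reads)
    class_fraction_mirna: float = 0.31
    class_fraction_structural: float = 0.09
    class_fraction_genic: float = 0.05

    # occupancy track: per-bin exon coverage probability and signal scale
    occupancy_cover: dict = field(
        default_factory=lambda: {"first": 0.94, "internal": 0.65, "last": 0.54, "single": 0.66}
    )
    occupancy_units_first: float = 130.0
    occupancy_units_other: float = 15.0

    # CLASH track
    clash_coverage: float = 0.6  # fraction of genic reads attracting CLASH records
    clash_reads_per_hit: float = 5.0
    clash_len_mean: float = 40.0

    # clone model: log-FC sigmas separated by ~an order of magnitude in
    # variance so the planted regimes are identifiable at this feature count
    n_features_per_subset: int = 200
    clone_names: tuple = ("wt", "clone5", "clone12")
    library_sizes: dict = field(
        default_factory=lambda: {"wt": 3090355, "clone5": 4432591, "clone12": 4714449}
    )
    fc_sigma_low: float = 0.15  # sigma of log FC, miRNA-like subset
    fc_sigma_mid: float = 0.45  # endo-siRNA-like
    fc_sigma_high: float = 1.0  # snoRNA-like
    fc_down_bias_high: float = -0.7  # mean log FC of the down-biased subset
    wt_count_log_mean: float = 6.0
    wt_count_log_sigma: float = 1.0

    def __post_init__(self):
        mix_total = sum(self.arrangement_mix.values())
        if not np.isclose(mix_total, 1.0):
            raise ValueError(f"arrangement_mix must sum to 1, got {mix_total}")
        for name in ("single_exon_gene_fraction", "sense_fraction", "sa_overlap_fraction",
                     "clash_coverage"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (MIN_READ_LEN <= self.length_peak <= MAX_READ_LEN):
            raise ValueError(f"length_peak must lie in [{MIN_READ_LEN}, {MAX_READ_LEN}]")


@dataclass
class Annotation:
    genes: list
    mirna: list
    structural: list
    planted_pairs: list  # (gene_id_left, gene_id_right, configuration, distance)
    chrom_length: int


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


def _gene_structure(config, rng, gene_id, chrom, start, strand) -> GeneModel:
    if rng.random() < config.single_exon_gene_fraction:
        n_exons = 1
    else:
        n_exons = 2 + rng.poisson(max(config.exon_count_mean - 2, 0))
    exons = []
    pos = start
    for i in range(n_exons):
        exon_len = config.exon_len_min + int(rng.exponential(config.exon_len_mean - config.exon_len_min))
        exons.append(GenomicInterval(chrom, pos, pos + exon_len, strand))
        pos += exon_len
        if i < n_exons - 1:
            pos += 1 + int(rng.exponential(config.intron_len_mean))
    body = GenomicInterval(chrom, start, exons[-1].end, strand)
    return GeneModel(gene_id, body, tuple(exons))


_PAIR_STRANDS = {
    HEAD_TO_HEAD: ((MINUS, PLUS),),
    TAIL_TO_TAIL: ((PLUS, MINUS),),
    TAIL_TO_HEAD: ((PLUS, PLUS), (MINUS, MINUS)),
}


def make_annotation(config: SimulationConfig) -> Annotation:
    """Generate gene models (as cassette pairs realizing the arrangement
    mix), miRNA and structural-RNA decoy annotations, deterministically per
    seed."""
    rng = _rng(config, "annotation")
    chrom = config.chrom
    n_pairs = config.n_genes // 2

    # exact-to-rounding realization of the arrangement mix
    labels = []
    for cfg_label in (HEAD_TO_HEAD, TAIL_TO_HEAD, TAIL_TO_TAIL):
        labels += [cfg_label] * int(round(config.arrangement_mix.get(cfg_label, 0.0) * n_pairs))
    while len(labels) < n_pairs:
        labels.append(TAIL_TO_HEAD)
    labels = labels[:n_pairs]
    rng.shuffle(labels)

    genes: list = []
    planted = []
    gaps = []  # inter-cassette gaps usable for decoys
    cursor = 1000
    for p, label in enumerate(labels):
        strands = _PAIR_STRANDS[label][rng.integers(len(_PAIR_STRANDS[label]))] \
            if label == TAIL_TO_HEAD else _PAIR_STRANDS[label][0]
        left = _gene_structure(config, rng, f"g{2 * p:04d}", chrom, cursor, strands[0])
        if label == TAIL_TO_TAIL and rng.random() < config.sa_overlap_fraction:
            distance = -int(rng.integers(1, max(config.exon_len_min // 2, 2)))
        else:
            distance = 1 + int(rng.exponential(config.mean_intergenic_distance))
        right_start = left.last_exon_end + distance
        right = _gene_structure(config, rng, f"g{2 * p + 1:04d}", chrom, right_start, strands[1])
        genes += [left, right]
        planted.append((left.gene_id, right.gene_id, label, distance))
        gap = int(
            config.inter_cassette_gap_factor * config.mean_intergenic_distance
            + rng.exponential(config.mean_intergenic_distance)
        )
        gaps.append((right.body.end + 50, right.body.end + gap - 50))
        cursor = right.body.end + gap
    if config.n_genes % 2:
        genes.append(_gene_structure(config, rng, f"g{config.n_genes - 1:04d}", chrom, cursor,
                                     PLUS if rng.random() < 0.5 else MINUS))
        cursor = genes[-1].body.end + 1000

    chrom_length = config.chrom_length or cursor + 10000
    if genes and genes[-1].body.end > chrom_length:
        raise ValueError(
            f"cannot pack {config.n_genes} genes into chrom_length={config.chrom_length}: "
            f"layout needs {genes[-1].body.end} bp"
        )

    # decoys dropped into inter-cassette gaps, non-overlapping
    mirna, structural = [], []
    if gaps:
        for out, n, length in ((mirna, config.n_mirna, config.mirna_len),
                               (structural, config.n_structural, config.structural_len)):
            for i in range(n):
                lo, hi = gaps[int(rng.integers(len(gaps)))]
                if hi - lo < length + 2:
                    continue
                start = int(rng.integers(lo, hi - length))
                out.append(GenomicInterval(chrom, start, start + length,
                                           PLUS if rng.random() < 0.5 else MINUS))
    return Annotation(genes, mirna, structural, planted, chrom_length)


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------


def length_weights(config: SimulationConfig) -> np.ndarray:
    """Planted length profile over 16..30: a triangular peak of the
    configured width on a small uniform baseline."""
    lengths = np.arange(MIN_READ_LEN, MAX_READ_LEN + 1)
    tri = np.maximum(0.0, config.length_width + 1 - np.abs(lengths - config.length_peak))
    w = tri + config.length_baseline * tri.max()
    return w / w.sum()


def _place_read_in_exon(rng, exon: GenomicInterval, length: int, strand: str) -> GenomicInterval:
    if exon.length <= length:
        start = exon.start
        length = min(length, exon.length)
    else:
        start = int(rng.integers(exon.start, exon.end - length))
    return GenomicInterval(exon.chrom, start, start + length, strand)


def _draw_genic_read(config, rng, gene: GeneModel, lengths, lw) -> tuple:
    """One read in ``gene``: exon bin by planted weights, length by planted
    profile, strand sense with the planted probability. Returns
    (read, bin_name)."""
    length = int(rng.choice(lengths, p=lw))
    if gene.n_exons == 1:
        exon, bin_name = gene.exons[0], "single"
    else:
        w = np.array(config.exon_bin_weights, dtype=float)
        if gene.n_exons == 2:
            w = np.array([config.exon_bin_weights[0], 0.0, config.exon_bin_weights[2]])
        w = w / w.sum()
        bin_name = ("first", "internal", "last")[int(rng.choice(3, p=w))]
        if bin_name == "first":
            exon = gene.five_prime_exon
        elif bin_name == "last":
            exon = gene.three_prime_exon
        else:
            internal = [e for e in gene.exons if e not in (gene.exons[0], gene.exons[-1])]
            exon = internal[int(rng.integers(len(internal)))]
    sense = rng.random() < config.sense_fraction
    strand = gene.strand if sense else (MINUS if gene.strand == PLUS else PLUS)
    return _place_read_in_exon(rng, exon, length, strand), bin_name


def make_reads(config: SimulationConfig, annotation: Annotation):
    """Stranded genic reads: per-gene abundances are heavy-tailed
    (log-normal), positions follow the exon-bin weights, lengths the
    planted profile, and orientation the planted sense fraction.

    Returns ``(reads, truth)``; ``truth`` records per-gene counts and every
    planted parameter the pipeline should recover.
    """
    rng = _rng(config, "reads")
    genes = annotation.genes
    weights = rng.lognormal(0.0, config.abundance_sigma, size=len(genes))
    weights /= weights.sum()
    counts = rng.multinomial(config.n_reads, weights)
    lengths = np.arange(MIN_READ_LEN, MAX_READ_LEN + 1)
    lw = length_weights(config)
    reads = []
    per_gene: dict = {}
    n_sense = 0
    for gene, n in zip(genes, counts):
        per_gene[gene.gene_id] = int(n)
        for _ in range(n):
            read, _bin = _draw_genic_read(config, rng, gene, lengths, lw)
            if read.strand == gene.strand:
                n_sense += 1
            reads.append(read)
    truth = {
        "per_gene_counts": per_gene,
        "sense_fraction": config.sense_fraction,
        "realized_sense_fraction": n_sense / len(reads) if reads else float("nan"),
        "length_peak": config.length_peak,
        "exon_bin_weights": list(config.exon_bin_weights),
        "n_reads": len(reads),
    }
    return reads, truth


def make_class_mixture(config: SimulationConfig, annotation: Annotation, n_reads: Optional[int] = None):
    """A mixed read population with planted class fractions: reads inside
    miRNA decoys, structural decoys, gene exons, and intergenic space (the
    nongenic remainder). Returns ``(reads, truth_fractions)``."""
    rng = _rng(config, "mixture")
    n = n_reads or config.n_reads
    fr = {
        "mirna": config.class_fraction_mirna,
        "structural": config.class_fraction_structural,
        "genic": config.class_fraction_genic,
    }
    fr["nongenic"] = 1.0 - sum(fr.values())
    if fr["nongenic"] < 0:
        raise ValueError("class fractions exceed 1")
    counts = rng.multinomial(n, [fr["mirna"], fr["structural"], fr["genic"], fr["nongenic"]])
    lengths = np.arange(MIN_READ_LEN, MAX_READ_LEN + 1)
    lw = length_weights(config)

    occupied = sorted(
        [(g.body.start, g.body.end) for g in annotation.genes]
        + [(iv.start, iv.end) for iv in annotation.mirna + annotation.structural]
    )
    reads = []
    for cls, k in zip(("mirna", "structural", "genic", "nongenic"), counts):
        for _ in range(k):
            length = int(rng.choice(lengths, p=lw))
            strand = PLUS if rng.random() < 0.5 else MINUS
            if cls == "mirna":
                host = annotation.mirna[int(rng.integers(len(annotation.mirna)))]
                reads.append(_place_read_in_exon(rng, host, length, strand))
            elif cls == "structural":
                host = annotation.structural[int(rng.integers(len(annotation.structural)))]
                reads.append(_place_read_in_exon(rng, host, length, strand))
            elif cls == "genic":
                gene = annotation.genes[int(rng.integers(len(annotation.genes)))]
                read, _ = _draw_genic_read(config, rng, gene, lengths, lw)
                reads.append(read)
            else:
                reads.append(_intergenic_read(rng, occupied, annotation.chrom_length,
                                              config.chrom, length, strand))
    return reads, fr


def _intergenic_read(rng, occupied, chrom_length, chrom, length, strand, max_tries=1000):
    for _ in range(max_tries):
        start = int(rng.integers(0, chrom_length - length))
        end = start + length
        if not any(s < end and start < e for s, e in occupied):
            return GenomicInterval(chrom, start, end, strand)
    raise RuntimeError("could not place an intergenic read; chromosome too crowded")


# ---------------------------------------------------------------------------
# Tracks
# ---------------------------------------------------------------------------


def make_tracks(config: SimulationConfig, annotation: Annotation, reads: Optional[Sequence] = None):
    """Occupancy bedGraph segments (signal concentrated on 5' first exons)
    and sparse CLASH reads coupled to a configured fraction of the genic
    reads. Returns ``(occupancy_segments, clash_reads)``."""
    rng = _rng(config, "tracks")
    segments = []
    for gene in annotation.genes:
        for i, exon in enumerate(gene.exons):
            if gene.n_exons == 1:
                key, hot = "single", False
            else:
                b = gene.exon_bin_of(i).value
                key = {"first_5p": "first", "last_3p": "last", "internal": "internal"}[b]
                hot = key == "first"
            if rng.random() >= config.occupancy_cover[key]:
                continue
            mean = config.occupancy_units_first if hot else config.occupancy_units_other
            units = float(rng.exponential(mean))
            segments.append(OccupancySegment(GenomicInterval(exon.chrom, exon.start, exon.end), units))
    segments.sort(key=lambda s: (s.span.chrom, s.span.start))

    clash = []
    if reads:
        idx = np.arange(len(reads))
        chosen = rng.random(len(reads)) < config.clash_coverage
        for i in idx[chosen]:
            read = reads[i]
            k = 1 + rng.poisson(max(config.clash_reads_per_hit - 1, 0))
            for _ in range(int(k)):
                length = max(18, int(rng.exponential(config.clash_len_mean)))
                jitter = int(rng.integers(-length + 1, read.length))
                start = max(0, read.start + jitter)
                clash.append(GenomicInterval(read.chrom, start, start + length,
                                             PLUS if rng.random() < 0.5 else MINUS))
    clash.sort()
    return segments, clash


# ---------------------------------------------------------------------------
# Clone counts
# ---------------------------------------------------------------------------


def make_clone_counts(config: SimulationConfig):
    """Three-clone raw count table with three planted fold-change variance
    regimes: ``low`` (tightly controlled, miRNA-like), ``mid``
    (endo-siRNA-like) and ``high`` (redundant, down-biased, snoRNA-like).

    Returns ``(raw_counts DataFrame, library_sizes, truth)``.
    """
    rng = _rng(config, "clones")
    wt_name, *others = config.clone_names
    sizes = config.library_sizes
    subsets = {
        "low": (config.fc_sigma_low, 0.0),
        "mid": (config.fc_sigma_mid, 0.0),
        "high": (config.fc_sigma_high, config.fc_down_bias_high),
    }
    rows = {}
    subset_of = {}
    for subset, (sigma, bias) in subsets.items():
        for i in range(config.n_features_per_subset):
            fid = f"{subset}_{i:04d}"
            subset_of[fid] = subset
            wt_cpm = rng.lognormal(config.wt_count_log_mean, config.wt_count_log_sigma)
            row = {wt_name: wt_cpm * sizes[wt_name] / 1e6}
            for clone in others:
                fc = rng.lognormal(bias, sigma)
                row[clone] = wt_cpm * fc * sizes[clone] / 1e6
            rows[fid] = row
    raw = pd.DataFrame.from_dict(rows, orient="index").round().astype(int)
    raw.index.name = "feature_id"
    raw = raw[list(config.clone_names)]
    truth = {
        "subset_of": subset_of,
        "fc_sigma": {k: v[0] for k, v in subsets.items()},
        "fc_bias": {k: v[1] for k, v in subsets.items()},
        "reference": wt_name,
    }
    return raw, dict(sizes), truth


# ---------------------------------------------------------------------------
# Bundle writer
# ---------------------------------------------------------------------------


def nat_categories_for(annotation: Annotation) -> dict:
    """Planted NAT category per gene: members of overlapping convergent
    pairs are SA, members of head-to-head pairs NOB, everything else NBD."""
    cats = {g.gene_id: "NBD" for g in annotation.genes}
    for left, right, label, distance in annotation.planted_pairs:
        if label == TAIL_TO_TAIL and distance < 0:
            cats[left] = cats[right] = "SA"
        elif label == HEAD_TO_HEAD:
            cats[left] = cats[right] = "NOB"
    return cats


def write_bundle(config: SimulationConfig, out_dir) -> dict:
    """Write a complete synthetic input bundle (GTF, BED6, bedGraph, TSV)
    plus a ground-truth manifest JSON; returns the file paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    annotation = make_annotation(config)
    reads, read_truth = make_reads(config, annotation)
    occupancy, clash = make_tracks(config, annotation, reads)
    raw, sizes, clone_truth = make_clone_counts(config)

    paths = {k: out / v for k, v in {
        "genes": "genes.gtf", "mirna": "mirna.bed", "structural": "structural.bed",
        "reads": "reads.bed", "occupancy": "occupancy.bedgraph", "clash": "clash.bed",
        "clone_counts": "clone_counts.tsv", "library_sizes": "library_sizes.tsv",
        "nat_categories": "nat_categories.tsv", "manifest": "manifest.json",
    }.items()}

    write_gtf(paths["genes"], annotation.genes)
    write_bed(paths["mirna"], [BedRecord(iv, f"mir{i}") for i, iv in enumerate(annotation.mirna)])
    write_bed(paths["structural"],
              [BedRecord(iv, f"sno{i}") for i, iv in enumerate(annotation.structural)])
    write_bed(paths["reads"], [BedRecord(iv, f"r{i}") for i, iv in enumerate(reads)])
    write_bedgraph(paths["occupancy"], occupancy)
    write_bed(paths["clash"], [BedRecord(iv, f"c{i}") for i, iv in enumerate(clash)])
    raw.to_csv(paths["clone_counts"], sep="\t")
    with open(paths["library_sizes"], "w") as fh:
        for clone, size in sizes.items():
            fh.write(f"{clone}\t{int(size)}\n")
    cats = nat_categories_for(annotation)
    with open(paths["nat_categories"], "w") as fh:
        for gid in sorted(cats):
            fh.write(f"{gid}\t{cats[gid]}\n")

    manifest = {
        "config": asdict(config),
        "planted_pairs": annotation.planted_pairs,
        "chrom_length": annotation.chrom_length,
        "reads": read_truth,
        "clones": clone_truth,
        "nat_categories": cats,
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return {k: str(v) for k, v in paths.items()}
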