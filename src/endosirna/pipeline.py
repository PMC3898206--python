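"""End-to-end orchestration: load inputs, run every analysis stage whose
inputs are present, and write Table-style TSV reports plus a provenance
copy of the configuration and a per-stage log."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import classification as cls
from . import clone_stability as stab
from . import gene_context as ctx
from . import intersection as ixs
from .intervals import read_bed, read_bedgraph, read_gene_models

logger = logging.getLogger("endosirna")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class RunConfig:
    """Inputs and thresholds of a pipeline run. Stages whose inputs are
    absent are skipped; thresholds default to the standard analysis
    settings (16-30 nt filter, >5 bidirectional, 2-fold, >100 reference
    reads, 1 bp minimum overlap)."""

    out_dir: str = "endosirna_out"
    reads_bed: Optional[str] = None
    genes_path: Optional[str] = None
    mirna_bed: Optional[str] = None
    structural_bed: Optional[str] = None
    occupancy_bedgraph: Optional[str] = None
    clash_bed: Optional[str] = None
    nat_table: Optional[str] = None
    nat_background: Optional[str] = None
    clone_counts_tsv: Optional[str] = None
    library_sizes_tsv: Optional[str] = None

    min_len: int = 16
    max_len: int = 30
    bidirectional_threshold: int = 5
    fold_threshold: float = 2.0
    pseudocount: float = 1.0
    min_reference_count: float = 100
    reference_clone: str = "wt"
    min_overlap_bp: int = 1
    unit_rule: str = "prorated"
    stringency_mode: Optional[str] = None  # units_threshold | percentile
    stringency_value: float = 0.0
    outlier_max_fraction: Optional[float] = None
    exclude_genes: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.min_len > self.max_len:
            raise ValueError("min_len must not exceed max_len")
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must be > 1")
        if self.min_overlap_bp < 1:
            raise ValueError("min_overlap_bp must be >= 1")
        if self.unit_rule not in ixs.UNIT_RULES:
            raise ValueError(f"unit_rule must be one of {ixs.UNIT_RULES}")
        if self.stringency_mode not in (None, "units_threshold", "percentile"):
            raise ValueError("stringency_mode must be units_threshold or percentile")
        if self.outlier_max_fraction is not None and not (0 < self.outlier_max_fraction <= 1):
            raise ValueError("outlier_max_fraction must be in (0, 1]")


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                logger.info("stage %s: start", name)
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name}: {exc}") from exc
        return wrapper
    return deco


def _profile_frame(expanded, collapsed):
    return pd.DataFrame({
        "length": expanded.lengths,
        "expanded_count": expanded.counts,
        "collapsed_count": collapsed.counts,
    })


@_stage("load_inputs")
def _load(config: RunConfig) -> dict:
    data: dict = {}
    if config.reads_bed:
        data["reads"] = [r.interval for r in read_bed(config.reads_bed)]
        logger.info("loaded %d reads", len(data["reads"]))
    if config.genes_path:
        data["genes"] = read_gene_models(config.genes_path)
        logger.info("loaded %d gene models", len(data["genes"]))
    data["mirna"] = [r.interval for r in read_bed(config.mirna_bed)] if config.mirna_bed else []
    data["structural"] = (
        [r.interval for r in read_bed(config.structural_bed)] if config.structural_bed else []
    )
    if config.occupancy_bedgraph:
        data["occupancy"] = read_bedgraph(config.occupancy_bedgraph)
    if config.clash_bed:
        data["clash"] = [r.interval for r in read_bed(config.clash_bed)]
    if config.nat_table:
        data["nat"] = ctx.read_nat_table(config.nat_table)
    if config.nat_background:
        df = pd.read_csv(config.nat_background, sep="\t", header=None,
                         names=["category", "count"], comment="#")
        data["nat_background"] = dict(zip(df["category"], df["count"].astype(int)))
    if config.clone_counts_tsv:
        data["clone_counts"], _ = stab.read_count_table(config.clone_counts_tsv)
    if config.library_sizes_tsv:
        data["library_sizes"] = stab.read_library_sizes(config.library_sizes_tsv)
    return data


def run_all(config: RunConfig) -> dict:
    """Run every stage whose inputs are configured and write the report
    bundle into ``config.out_dir``. Returns the in-memory results.

    Deterministic given the configuration and input files; any stage error
    aborts the run with the stage name in the exception.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    results: dict = {}
    try:
        data = _load(config)
        with open(out / "run_config.json", "w") as fh:
            json.dump(dataclasses.asdict(config), fh, indent=1)

        if "reads" in data and "genes" in data:
            _classification_stages(config, data, results, out)
            if "occupancy" in data or "clash" in data:
                _intersection_stages(config, data, results, out)
        if "genes" in data:
            _context_stages(config, data, results, out)
        if "clone_counts" in data and "library_sizes" in data:
            _clone_stages(config, data, results, out)
        summary = {
            k: v for k, v in results.items()
            if isinstance(v, (int, float, str)) and not isinstance(v, bool)
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return results


@_stage("classification")
def _classification_stages(config, data, results, out):
    breakdown = cls.categorize_reads(data["reads"], data["mirna"], data["structural"], data["genes"])
    pd.DataFrame({
        "read_class": list(breakdown.counts),
        "count": list(breakdown.counts.values()),
        "fraction": [breakdown.fractions[c] for c in breakdown.counts],
    }).to_csv(out / "class_breakdown.tsv", sep="\t", index=False)
    results["class_breakdown"] = breakdown
    logger.info("class counts: %s", breakdown.counts)

    genic = cls.length_filter(breakdown.reads["genic"], config.min_len, config.max_len)
    collapsed = cls.collapse_reads(genic)
    logger.info("genic 16-30nt reads: %d expanded, %d collapsed", len(genic), len(collapsed))

    assigned, ambiguous = cls.assign_reads_to_genes(collapsed, data["genes"])
    results["n_ambiguous_gene_assignment"] = len(ambiguous)

    orient = cls.orientation_summary(assigned, data["genes"], config.bidirectional_threshold)
    pd.DataFrame(
        [(r.gene_id, r.sense_reads, r.antisense_reads, r.bidirectional_flag)
         for r in orient.records],
        columns=["gene_id", "sense", "antisense", "bidirectional"],
    ).to_csv(out / "orientation.tsv", sep="\t", index=False)
    results["sense_fraction"] = orient.sense_fraction
    logger.info("global sense fraction: %.4f", orient.sense_fraction)

    per_gene = {}
    for read, gid in assigned:
        per_gene[gid] = per_gene.get(gid, 0) + read.multiplicity
    excluded = cls.flag_outlier_genes(
        per_gene,
        max_fraction=config.outlier_max_fraction or 1.0,
        explicit=config.exclude_genes or (None if config.outlier_max_fraction else []),
    )
    results["excluded_genes"] = sorted(excluded)
    logger.info("excluded outlier genes: %s", sorted(excluded))
    kept = [(r, g) for r, g in assigned if g not in excluded]

    kept_reads = [r for r, _ in kept]
    expanded = cls.length_profile(kept_reads)
    collapsed_profile = cls.length_profile(kept_reads, collapsed=True)
    _profile_frame(expanded, collapsed_profile).to_csv(out / "length_profile.tsv", sep="\t", index=False)
    results["length_profile"] = expanded
    results["length_peak"] = expanded.peak_length

    results["binned_reads"] = cls.bin_reads_by_exon(kept, data["genes"])
    results["per_gene_counts"] = per_gene


@_stage("intersection")
def _intersection_stages(config, data, results, out):
    binned = results["binned_reads"]
    if "occupancy" in data:
        occ = ixs.summarize_occupancy(binned, data["occupancy"], rule=config.unit_rule,
                                      min_overlap_bp=config.min_overlap_bp)
        ixs.occupancy_table(occ).to_csv(out / "occupancy_summary.tsv", sep="\t", index=False)
        results["occupancy_summary"] = occ
        all_reads = [r for reads in binned.values() for r in reads]
        hit, miss = ixs.profile_by_overlap(all_reads, [s.span for s in data["occupancy"]],
                                           min_overlap_bp=config.min_overlap_bp)
        _profile_frame(hit, miss).rename(columns={
            "expanded_count": "overlapping", "collapsed_count": "non_overlapping"
        }).to_csv(out / "occupancy_length_split.tsv", sep="\t", index=False)
        if config.stringency_mode:
            stringent = ixs.stringency_filter(all_reads, data["occupancy"],
                                              config.stringency_mode, config.stringency_value,
                                              rule=config.unit_rule)
            results["n_stringent_reads"] = len(stringent)
            prof = cls.length_profile(stringent)
            pd.DataFrame({"length": prof.lengths, "count": prof.counts}).to_csv(
                out / "stringent_length_profile.tsv", sep="\t", index=False)
    if "clash" in data:
        clash = ixs.summarize_clash(binned, data["clash"], min_overlap_bp=config.min_overlap_bp)
        ixs.clash_table(clash).to_csv(out / "clash_summary.tsv", sep="\t", index=False)
        results["clash_summary"] = clash


@_stage("gene_context")
def _context_stages(config, data, results, out):
    pairs = ctx.neighbor_pairs(data["genes"], results.get("per_gene_counts"))
    pd.DataFrame(
        [(p.gene_id, p.neighbor_id, p.configuration, p.distance, p.focal_read_count)
         for p in pairs],
        columns=["gene_id", "neighbor_id", "configuration", "distance", "read_count"],
    ).to_csv(out / "neighbor_pairs.tsv", sep="\t", index=False)
    results["neighbor_pairs"] = pairs

    fits = []
    for conf in ctx.CONFIGURATIONS:
        try:
            fit = ctx.distance_readcount_fit(pairs, configuration_filter=conf)
            fits.append((conf, fit.slope, fit.intercept, fit.r_squared, fit.n))
        except ValueError:
            logger.info("fit skipped for %s: <3 pairs", conf)
    if fits:
        pd.DataFrame(fits, columns=["configuration", "slope", "intercept", "r_squared", "n"]) \
            .to_csv(out / "distance_fits.tsv", sep="\t", index=False)
        results["distance_fits"] = fits

    if "nat" in data and "nat_background" in data:
        focal_genes = results.get("per_gene_counts") or {g.gene_id: 1 for g in data["genes"]}
        focal = {gid: c for gid, c in data["nat"].items() if gid in focal_genes}
        enrichment = ctx.nat_enrichment(focal, data["nat_background"], test=True)
        enrichment.table.to_csv(out / "nat_enrichment.tsv", sep="\t", index=False)
        results["nat_enrichment"] = enrichment


@_stage("clone_stability")
def _clone_stages(config, data, results, out):
    report = stab.stability_report(
        data["clone_counts"], data["library_sizes"], config.reference_clone,
        fold_threshold=config.fold_threshold, pseudocount=config.pseudocount,
        min_reference_count=config.min_reference_count,
    )
    frame = report.fractions.copy()
    frame.index.name = "clone"
    frame.to_csv(out / "stability.tsv", sep="\t")
    results["stability"] = report
    results["pooled_variance"] = report.pooled_variance
    logger.info("pooled variance: %.4f", report.pooled_variance)
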