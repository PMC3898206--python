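"""The synthetic-data generators: determinism, planted structure, and
parameter recovery by the corresponding pipeline stages."""

import json

import numpy as np
import pandas as pd
import pytest

from endosirna import (
    ExonBin,
    SimulationConfig,
    categorize_reads,
    classify_exon_bin,
    make_annotation,
    make_class_mixture,
    make_clone_counts,
    make_reads,
    make_tracks,
    neighbor_pairs,
    pooled_variance,
    write_bundle,
)
from endosirna.gene_context import TAIL_TO_TAIL
from endosirna.simulate import length_weights, nat_categories_for


SMALL = dict(n_genes=40, n_reads=2000)


class TestDeterminism:
    def test_same_seed_byte_identical_bundles(self, tmp_path):
        config = SimulationConfig(seed=7, **SMALL)
        p1 = write_bundle(config, tmp_path / "a")
        p2 = write_bundle(config, tmp_path / "b")
        for key in p1:
            assert open(p1[key]).read().replace(str(tmp_path / "a"), "") == \
                   open(p2[key]).read().replace(str(tmp_path / "b"), "")

    def test_distinct_seeds_differ(self):
        r1, _ = make_reads(SimulationConfig(seed=1, **SMALL),
                           make_annotation(SimulationConfig(seed=1, **SMALL)))
        r2, _ = make_reads(SimulationConfig(seed=2, **SMALL),
                           make_annotation(SimulationConfig(seed=2, **SMALL)))
        assert r1 != r2


class TestAnnotation:
    def test_forced_tail_to_tail_mix(self):
        config = SimulationConfig(seed=3, n_genes=10,
                                  arrangement_mix={TAIL_TO_TAIL: 1.0})
        ann = make_annotation(config)
        assert len(ann.planted_pairs) == 5
        assert all(label == TAIL_TO_TAIL for _, _, label, _ in ann.planted_pairs)
        # planted pairs are recovered as convergent adjacencies by the analysis
        by_pair = {(p.gene_id, p.neighbor_id): p for p in neighbor_pairs(ann.genes)}
        for left, right, _, distance in ann.planted_pairs:
            rec = by_pair[(left, right)]
            assert rec.configuration == TAIL_TO_TAIL
            assert rec.distance == distance

    def test_mean_intergenic_distance_recovered(self):
        config = SimulationConfig(seed=5, n_genes=1000, mean_intergenic_distance=5000)
        ann = make_annotation(config)
        distances = [d for _, _, _, d in ann.planted_pairs]
        assert np.mean(distances) == pytest.approx(5000, rel=0.10)

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError, match="pack"):
            make_annotation(SimulationConfig(seed=0, n_genes=50, chrom_length=10_000))

    def test_gene_models_valid_and_sorted(self):
        ann = make_annotation(SimulationConfig(seed=9, **SMALL))
        starts = [g.body.start for g in ann.genes]
        assert starts == sorted(starts)
        assert all(g.exons for g in ann.genes)


class TestReads:
    def test_forced_sense_fraction(self):
        config = SimulationConfig(seed=2, sense_fraction=1.0, **SMALL)
        ann = make_annotation(config)
        reads, _ = make_reads(config, ann)
        genes = {g.gene_id: g for g in ann.genes}
        strand_of = {}
        for g in ann.genes:
            for e in g.exons:
                strand_of[(e.start, e.end)] = g.strand
        assert all(any(e.start <= r.start and r.end <= e.end and r.strand == g.strand
                       for g in ann.genes for e in g.exons) for r in reads[:200])

    def test_forced_first_exon_placement(self):
        config = SimulationConfig(seed=4, exon_bin_weights=(1.0, 0.0, 0.0),
                                  single_exon_gene_fraction=0.0, **SMALL)
        ann = make_annotation(config)
        reads, _ = make_reads(config, ann)
        genes = {g.gene_id: g for g in ann.genes}
        # every read must classify FIRST_5P in its source gene
        for r in reads[:300]:
            host = next(g for g in ann.genes
                        if g.body.start <= r.start and r.end <= g.body.end)
            assert classify_exon_bin(r, host) is ExonBin.FIRST_5P

    def test_length_peak_planted(self):
        config = SimulationConfig(seed=6, length_peak=22, **SMALL)
        ann = make_annotation(config)
        reads, _ = make_reads(config, ann)
        lengths = [r.length for r in reads]
        values, counts = np.unique(lengths, return_counts=True)
        assert values[np.argmax(counts)] == 22

    def test_length_weights_normalized_peaked(self):
        w = length_weights(SimulationConfig(length_peak=24))
        assert w.sum() == pytest.approx(1.0)
        assert np.argmax(w) == 24 - 16


class TestMixture:
    def test_planted_class_fractions_recovered(self):
        config = SimulationConfig(seed=11, n_genes=60,
                                  class_fraction_mirna=0.30,
                                  class_fraction_structural=0.09,
                                  class_fraction_genic=0.01)
        ann = make_annotation(config)
        reads, truth = make_class_mixture(config, ann, n_reads=100_000)
        bd = categorize_reads(reads, ann.mirna, ann.structural, ann.genes)
        for cls in ("mirna", "structural", "genic"):
            assert bd.fractions[cls] == pytest.approx(truth[cls], abs=0.005)


class TestTracks:
    def test_occupancy_biased_to_first_exons(self):
        config = SimulationConfig(seed=13, n_genes=100, n_reads=2000)
        ann = make_annotation(config)
        occupancy, _ = make_tracks(config, ann)
        first_spans = {(g.five_prime_exon.start, g.five_prime_exon.end)
                       for g in ann.genes if g.n_exons > 1}
        hot = [s.units for s in occupancy if (s.span.start, s.span.end) in first_spans]
        cold = [s.units for s in occupancy if (s.span.start, s.span.end) not in first_spans]
        assert np.mean(hot) > 3 * np.mean(cold)

    def test_clash_coupled_to_reads(self):
        config = SimulationConfig(seed=14, clash_coverage=0.5, **SMALL)
        ann = make_annotation(config)
        reads, _ = make_reads(config, ann)
        _, clash = make_tracks(config, ann, reads)
        assert clash, "clash track should not be empty when reads are supplied"
        _, empty_clash = make_tracks(config, ann, None)
        assert empty_clash == []


class TestCloneCounts:
    def test_planted_variance_regimes_ordered(self):
        config = SimulationConfig(seed=15)
        raw, sizes, truth = make_clone_counts(config)
        norm = raw * 1e6 / pd.Series(sizes)
        fc = norm[["clone5", "clone12"]].div(norm["wt"], axis=0)
        pv = {s: pooled_variance(fc.loc[[f for f, sub in truth["subset_of"].items() if sub == s]])
              for s in ("low", "mid", "high")}
        assert pv["low"] < pv["mid"] < pv["high"]

    def test_high_subset_down_biased(self):
        config = SimulationConfig(seed=16)
        raw, sizes, truth = make_clone_counts(config)
        norm = raw * 1e6 / pd.Series(sizes)
        fc = norm[["clone5"]].div(norm["wt"], axis=0)["clone5"]
        high = [f for f, s in truth["subset_of"].items() if s == "high"]
        low = [f for f, s in truth["subset_of"].items() if s == "low"]
        assert fc.loc[high].median() < fc.loc[low].median()


def test_manifest_records_planted_parameters(tmp_path):
    config = SimulationConfig(seed=21, **SMALL)
    paths = write_bundle(config, tmp_path)
    manifest = json.load(open(paths["manifest"]))
    assert manifest["config"]["sense_fraction"] == config.sense_fraction
    assert manifest["reads"]["length_peak"] == 22
    assert set(manifest["nat_categories"]) == {g.gene_id for g in
                                               make_annotation(config).genes}


def test_nat_categories_follow_pair_geometry():
    config = SimulationConfig(seed=22, n_genes=40, sa_overlap_fraction=1.0,
                              arrangement_mix={TAIL_TO_TAIL: 1.0})
    ann = make_annotation(config)
    cats = nat_categories_for(ann)
    assert set(cats.values()) == {"SA"}
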