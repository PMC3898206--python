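# endosirna

Strand-aware profiling of genic endogenous short interfering RNAs
(endo-siRNAs) from short-RNA sequencing alignments.

Differentiated human cells express a sparse layer of ~20–25 nt RNAs that map
to exons of protein-coding genes. A natural question is where these RNAs come
from: stalled RNA polymerase II at gene ends, the RNA-interference machinery
(Argonaute loading), or convergent transcription of neighboring genes
producing sense/antisense (NAT) duplexes. `endosirna` implements the
computational side of that question as a reusable, tested pipeline for anyone
with strand-aware alignments (BED6) and a gene annotation (GTF/BED12):

* **Read classification** — each aligned read is assigned to exactly one
  class with priority miRNA > structural RNA > genic (exonic) > other-genic >
  nongenic; genic reads are filtered to 16 ≤ length ≤ 30 nt, collapsed to
  unique spans with multiplicities, profiled by length, and summarized per
  gene by orientation (a read is *sense* when its strand equals the gene
  strand; a gene is *bidirectional* when both orientations strictly exceed a
  count threshold, default 5). Genes that dominate the dataset can be
  excluded explicitly or by a greedy cumulative-share rule.
* **Exon-position binning and intersection statistics** — collapsed reads are
  binned into first 5′ exon / internal / last 3′ exon / single-exon-gene
  (maximal-overlap rule, strand-aware), then intersected with an occupancy
  signal track (e.g. RNAPII ChIP-seq bedGraph) and with a CLASH interval set
  (Argonaute-bound reads). Per bin the pipeline reports
  `percent = 100 · overlapping/total`, `average units = Σ units / total`,
  and `CLASH/siRNA = clash reads / intersected siRNA reads`, rounded
  half-away-from-zero to one decimal.
* **Gene context** — adjacent gene pairs are classified as head-to-head
  (divergent), tail-to-head (tandem) or tail-to-tail (convergent), with the
  inter-gene distance `start(first exon of following gene) − end(last exon of
  preceding gene)`; read counts are regressed on distance (OLS, R²), and NAT
  categories (SA / NOB / NBD) are compared between the focal gene set and the
  genomic background as column percentages.
* **Clone stability** — counts-per-million normalization against total
  library sizes, per-feature fold changes versus a reference clone, 2-fold
  up/down/unchanged fractions, and the pooled variance
  `Σ(nᵢ−1)sᵢ² / Σ(nᵢ−1)` of fold changes as a single stability readout.
* **Synthetic data** — a seeded generator produces every input the pipeline
  consumes (gene models, decoy annotations, stranded reads, occupancy and
  CLASH tracks, clone count tables) with planted, recoverable structure and a
  ground-truth manifest, so the whole pipeline is testable offline.

Coordinates are 0-based half-open (BED convention) throughout; GTF input is
converted at the file boundary.

## Worked example

Generate a synthetic study (seed 7: 200 genes, 10 000 genic reads with a
planted 22 nt length peak, 69.4 % sense orientation and 5′-biased occupancy)
and run the full pipeline on it:

```sh
endosirna simulate --seed 7 --out-dir sim
endosirna run-all \
    --reads sim/reads.bed --genes sim/genes.gtf \
    --mirna sim/mirna.bed --structural sim/structural.bed \
    --occupancy sim/occupancy.bedgraph --clash sim/clash.bed \
    --counts sim/clone_counts.tsv --library-sizes sim/library_sizes.tsv \
    --out-dir out
```

prints

```
sense_fraction	0.6983
length_peak	22
pooled_variance	0.3657
reports written to out
```

— the planted 69.4 % sense orientation and the 22 nt peak are recovered from
the generated reads, and the pooled variance summarizes fold-change spread
across the two simulated mutagenized clones. `out/occupancy_summary.tsv`
shows the planted 5′ occupancy coupling:

```
bin	integrated_units	total_sirna_reads	average_units	reads_with_occupancy	percent
Total reads	46141.6	9641	4.8	6951	72.1
5'	35228.2	2323	15.2	2281	98.2
3'	3952.7	3540	1.1	1993	56.3
Internal exons	2244.7	1972	1.1	1111	56.3
1 exon genes	4716.0	1806	2.6	1566	86.7
Others	0.0	0	0.0	0	0.0
```

reads in the first 5′ exon co-localize with the occupancy signal far more
often (98.2 %) and at much higher average signal (15.2 units) than reads in
the last exon (56.3 %, 1.1 units), exactly the structure the generator
planted. Other reports in `out/`: `class_breakdown.tsv`, `orientation.tsv`,
`length_profile.tsv`, `clash_summary.tsv`, `neighbor_pairs.tsv`,
`distance_fits.tsv`, `stability.tsv`, plus `run_config.json` and `run.log`
for provenance.

The same analyses are available as library functions
(`endosirna.intersect`, `classify_exon_bin`, `categorize_reads`,
`summarize_occupancy`, `summarize_clash`, `neighbor_pairs`,
`nat_enrichment`, `stability_report`, …).

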