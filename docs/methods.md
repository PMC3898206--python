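# Methods

This note documents the models, conventions and numerical choices behind
`endosirna`, in the order the pipeline runs.

## Coordinates and intersection

All genomic spans are 0-based half-open (`[start, end)`, BED convention)
with strand `+`, `-` or `.` (unstranded). GTF input (1-based inclusive) is
converted at the file boundary; exons of all transcripts of a gene are
union-merged so each gene model carries non-overlapping, genomically sorted
exons. Abutting half-open intervals do not intersect; identical intervals
always do.

The intersection engine reports every interval pair sharing at least
`min_overlap_bp` bases (default 1 bp, the common bedtools-style convention;
no standard mandates another choice). Strand handling is explicit:
`ignore`, `same` or `opposite`; under the strand-aware modes a candidate
pair with an unstranded member is skipped and counted in a diagnostics
tally rather than silently matched. Output order is deterministic (a-index,
then b-index). Internally an interval tree provides the sweep; where only
"does anything overlap" is needed (CLASH summaries, length-profile splits)
the implementation uses merged-union binary search instead of enumerating
pairs, which keeps dense tracks from inducing quadratic work. The unit
tests check both paths against an independent all-pairs oracle.

## Read classification

Reads are assigned to exactly one class with priority **miRNA > structural
RNA > genic (exonic) > other-genic (gene body, intron only) > nongenic**.
A precedence is needed because annotations overlap (miRNA hairpins sit in
exons); putting miRNA first keeps hairpin-derived reads out of the
endo-siRNA totals, which is the analytically conservative choice. Class
overlap is strand-ignored with a 1 bp minimum.

The genic set is filtered to 16 ≤ length ≤ 30 nt, both bounds inclusive
(read length is the alignment span, `end − start`). Collapsing merges reads
identical in (chrom, start, end, strand); strand is part of read identity,
and total multiplicity is conserved — a property test asserts both.

Reads overlapping several genes go to the gene with the largest exonic
overlap; exact ties are set aside as ambiguous and tallied. Within a gene,
a read takes the bin (first 5′ exon / internal / last 3′ exon, mapped
through the gene strand; single-exon genes form their own bin) of the exon
it overlaps most, with exact cross-bin ties labelled OTHER. These
tie-breaking rules are deterministic operationalizations of steps that are
often done by eye in genome browsers; the OTHER bin is therefore reported
but never interpreted.

Outlier genes — a handful of loci can contribute most of a small-RNA
dataset — are excluded either by an explicit gene list (preferred, and
first-class in the API) or by a greedy rule: rank genes by count and flag
the smallest top-k whose cumulative share exceeds `max_fraction`; if only
the entire gene set exceeds it, nothing is disproportionate and nothing is
flagged. The rule flags {A} for counts {A: 63, B: 20, C: 17} at
`max_fraction = 0.5` and flags nothing for uniform counts.

Orientation: a read is sense when its strand equals the gene strand; the
global sense fraction is multiplicity-weighted. A gene is flagged
bidirectional when both orientations *strictly* exceed the threshold
(default 5 reads).

## Occupancy and CLASH intersection statistics

Per exon bin the occupancy summary reports total reads, reads sharing ≥1 bp
with any signal segment, `percent = 100 · overlapping / total`, the summed
"integrated units" and `average = units / total`. A read's units are, under
the default **prorated** rule, `Σ units × overlap_bp / segment_length` over
touched segments — attributing to the read only the fraction of each
segment it covers; a **full-segment** mode (sum of whole-segment units) is
a config switch, since reported aggregations of this kind rarely state the
rule. Occupancy intersection ignores strand (ChIP signal is unstranded).

The stringency filter keeps reads whose assigned units reach a cutoff given
either directly (units mode; the boundary read is kept, matching an
"exclude < cutoff" reading) or as a percentile of the per-read units
distribution. Both modes exist because either convention is defensible;
neither is declared canonical.

The CLASH summary counts, per bin, siRNA reads with at least one CLASH
overlap and distinct CLASH records touching the bin; a CLASH record
overlapping several siRNA reads of one bin counts once, so per-bin CLASH
tallies never exceed the CLASH library size. The ratio `clash /
intersected` is reported as NA when nothing intersects. CLASH intersection
is strand-ignored by default with a same-strand option (chimera-derived
reads do not carry a reliable strand guarantee).

Report tables round half-away-from-zero to one decimal — Python's built-in
banker's rounding would print 129.55 as 129.5 where summary tables of this
kind print 129.6. The TOTAL row is always recomputed over all reads, never
summed from the bin rows.

Length profiles are exact histograms over 16–30 nt (15 bins), expanded
(multiplicity-weighted) or collapsed (unique spans). Splitting reads by
overlap with a partner set yields two profiles that partition the total
bin-wise; this conservation is property-tested.

## Gene context

Adjacent gene pairs (nearest neighbor each side, per chromosome) are
classified from strand geometry: divergent 5′↔5′ head-to-head, tandem
same-strand tail-to-head, convergent 3′↔3′ tail-to-tail — only convergent
pairs can support exonic sense/antisense overlap. Distance is
`start(first exon of following gene) − end(last exon of preceding gene)`;
overlapping neighbors get a negative distance and are retained by default
(overlap is precisely what makes a sense/antisense pair), with an exclusion
switch. Both members of a pair yield the same configuration and distance.

Read count is regressed on distance by ordinary least squares
(`scipy.stats.linregress`), optionally per configuration and below a
caller-chosen distance cutoff — "near neighbor" has no agreed
definition, so no default is claimed. Counts can be fit as log2(count + 1);
the default is the untransformed scale. Fewer than 3 points is an error;
zero-variance distance leaves R² undefined (NaN).

NAT-category enrichment compares focal-set and background counts over SA
(sense/antisense overlapping), NOB (bidirectional non-overlapping) and NBD
(non-bidirectional) as column percentages (one decimal, half-away-from-zero;
columns sum to 100 ± rounding). An optional 3×2 chi-square test is provided
as plumbing beyond the percentage comparison.

## Clone stability

Normalization is counts-per-million against *total parsed reads per clone*
(not column sums), so feature filtering does not distort scale; CPM is the
minimal faithful choice where only "normalized read numbers" is specified.
Features are pre-filtered by reference-clone raw count strictly greater
than a threshold (default 100). Fold changes are
`(cpm + pseudocount) / (ref_cpm + pseudocount)` on the linear scale with
pseudocount 1 (zeros are otherwise undefined); a log2 option exists. A
feature is up-regulated when FC ≥ t and down when FC ≤ 1/t (default t = 2;
the exact boundary counts as changed — an arbitrary but flagged choice).
Up/down/unchanged fractions sum to 1 per clone by construction.

The pooled variance is `Σ(nᵢ−1)sᵢ² / Σ(nᵢ−1)` over per-clone sample
variances (ddof 1) of fold changes versus the reference; it equals the
ordinary sample variance for a single clone, clones with fewer than 2
usable features are skipped with a warning, and the statistic is undefined
(error) when every clone is skipped. Because the exact formulation of this readout used in reference
analyses (variance flavor, FC scale, feature filtering)
is not recoverable, no absolute pooled-variance value is asserted anywhere
— only the ordering of planted variance regimes.

## Synthetic data

The generator emulates the study conditions the pipeline targets and every
planted parameter is recoverable by the corresponding stage — the
generator's tests are the pipeline's parameter-recovery suite.

* **Gene layout.** Genes live on one synthetic chromosome (`chrS`) as
  disjoint cassette pairs. The configured head-to-head / tail-to-head /
  tail-to-tail mix is realized exactly (up to rounding) over the planted
  pairs, recorded in the manifest; intra-pair distances are exponential
  (default mean 5 kb) and inter-cassette gaps are drawn an order of
  magnitude larger. A linear gene chain cannot make every adjacency
  convergent — tail-to-tail (+,−) and head-to-head (−,+) adjacencies
  necessarily alternate — so extreme mixes are planted on the cassette
  pairs, not on every adjacency. About 10 % of genes are single-exon;
  multi-exon genes have 2 + Poisson exons of ≥ 80 bp, so every 16–30 nt
  read fits inside one exon and bin ground truth is unambiguous.
* **Reads.** Per-gene abundance is log-normal (σ = 1.3, heavy-tailed, so
  outlier exclusion has something to catch). Lengths follow a triangular
  peak at 22 nt (width 4) on a small baseline over 16–30 nt; orientation is
  sense with probability 0.694; placement follows exon-bin weights
  (0.253 / 0.225 / 0.378 for first/internal/last).
* **Tracks.** Occupancy segments cover exons with bin-dependent probability
  (first 0.94, internal 0.65, last 0.54, single 0.66) and exponential units
  (mean 130 on first exons, 15 elsewhere) — the planted 5′ coupling. CLASH
  records are generated around a configured fraction (0.6) of the reads,
  ~5 jittered records per hit.
* **Clones.** Three feature subsets plant fold-change regimes: log-FC σ of
  0.15 (tightly controlled, miRNA-like), 0.45 (intermediate,
  endo-siRNA-like) and 1.0 with a −0.7 log-mean down-bias (redundant,
  down-biased, snoRNA-like), 200 features each. The σ steps (~9× and ~5× in
  log-FC variance) are chosen so the planted low < intermediate < high
  pooled-variance ordering is statistically identifiable at this feature
  count — the sample variance of a heavy-tailed fold-change distribution is
  itself noisy, and closer regimes would not constitute recoverable ground
  truth. Library sizes default to 3.09/4.43/4.71 million.

All randomness flows from a single seed through fixed per-generator
substreams; the same seed yields byte-identical bundles. What the generator
does **not** emulate: sequence content and sequencing error, mappability
and multi-mapping, chromatin-domain correlation structure, inter-gene
abundance correlations, or real NAT biology — passing recovery tests shows
the pipeline measures what it claims on data with known structure, not that
any biological conclusion transfers to a particular real dataset.

## Problem sizes and determinism in the test suite

The default suites run the generator at 40–200 genes and 1 500–10 000
reads, 20 seeds for the stochastic ordering/coupling checks, and a
10³ × 10³ instance for engine-vs-oracle equivalence; these sizes give
stable statistics for every planted effect while keeping the whole suite
fast. Stochastic tests are seeded (numpy `default_rng`; hypothesis in
derandomized mode). The sense-fraction recovery tolerance is 3 binomial
standard errors at the configured read count; the length peak must be
recovered exactly.

## Known limitations

* The OTHER exon bin is this package's deterministic operationalization of
  reads that cannot be unambiguously assigned; counts in it are reported
  but not interpreted.
* The greedy outlier rule is one of several defensible formalizations of
  "a few genes dominate"; explicit exclusion lists are preferred.
* Occupancy unit attribution (prorated vs full-segment) changes average
  units but not percent overlap; comparisons across runs must fix the rule.
* `nat_enrichment` tests 3×2 association only; it does not model gene
  length or expression confounding.
* Neighbor analysis considers only the nearest gene on each side and does
  not handle nested genes specially.
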