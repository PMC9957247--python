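# Methods

## Pipeline model

The analysis unit is the CNVR: per-sample read-depth CNV calls,
filtered for confidence, are merged across samples by single-linkage —
any two calls sharing at least one base pair are connected, and
connected components (with transitive closure) become regions whose
interval is the component envelope. On 1-based fully inclusive
coordinates this is a start-sorted sweep; envelopes of distinct regions
are disjoint by construction, so each filtered call belongs to exactly
one CNVR. Regions are classified DEL (all member calls deletions), DUP
(all duplications) or BOTH (mixed).

Internal coordinates are 1-based inclusive throughout (the CNVnator
dialect). BED input/output is converted at the I/O boundary; GFF3
passes through unshifted. Chromosome names are taken verbatim from the
genome table, which also fixes reporting order.

### Call filtering

Four rules, all strict comparisons, each applied independently so the
rejection report counts every violated rule per call:

| parameter       | default | meaning                                   |
|-----------------|---------|-------------------------------------------|
| `max_e_value`   | 0.01    | call significance; first e-value column   |
| `del_rd_max`    | 0.7     | normalized read depth ceiling, deletions  |
| `dup_rd_min`    | 1.3     | normalized read depth floor, duplications |
| `min_length_bp` | 1000    | minimum call length, exclusive            |

Boundary values (RD exactly 0.7, length exactly 1000 bp) are rejected;
strictness is fixed rather than configurable so the behaviour stays
auditable. CNVnator emits several e-value columns; the parser takes the
first (the primary t-test value) by default, with the column index
configurable because call sets in the wild disagree about which column
matters.

### Copy-number estimation

The full-scale workflow genotypes copy number from raw depth signal;
here copy number per (region, sample) is estimated from the calls
themselves: `CN = 2 × length-weighted mean RD` over the region, where
base pairs covered by the sample's calls contribute the call RD and
uncovered base pairs contribute the diploid RD of 1.0. A sample with no
call in the region is exactly diploid (CN 2.0). Where one sample's
calls overlap inside a region, each base takes the mean RD of its
covering calls (elementary-segment walk). Copy numbers are kept
continuous; `round_cn=True` rounds to integers for sensitivity
analysis.

### VST

`VST = (V_total − (V1·N1 + V2·N2)/N_total) / V_total` with
denominator-`N` (population) variances. The `N` convention is the one
under which the formula is an exact between/total variance
decomposition, guaranteeing VST ∈ [0, 1] up to floating point; values
outside the interval are clamped and flagged. `V_total = 0` (every
sample identical) is defined as VST 0 and flagged degenerate rather
than 0/0. Exactly two populations are required; a third is an error,
not a silent pool.

### Percentile selection

The threshold for fraction *f* over *M* finite VST values is the
nearest-rank order statistic at rank ⌈(1−f)·M⌉; a region is selected
iff its VST ≥ threshold, so ties at the threshold are all included.
Thresholds are reported alongside the flags. With every value equal,
everything is selected at every fraction — the honest reading of a
distribution with no tail.

### Sample structure

PCA is the singular value decomposition of the column-centered
sample × CNVR matrix; variance explained is σᵢ²/Σσ², and each
component's sign is fixed by making its largest-magnitude loading
positive. The sample tree is UPGMA (scipy average-linkage on Euclidean
copy-number distances) serialized to Newick with ultrametric branch
lengths: a node's height is half its cophenetic merge distance, and a
child branch is the height difference. Samples are processed in
lexicographic id order so equal-distance merges resolve
deterministically.

### Annotation and enrichment

Gene/QTL overlap uses the same ≥ 1 bp criterion as merging (an interval
tree for lookup, validated in tests against an all-pairs scan), with
optional minimum-overlap and minimum-Jaccard filters. Enrichment is the
standard hypergeometric upper tail per term over a gene universe
(default: all genes in the annotation file), Benjamini–Hochberg
adjusted across tested terms; terms with no selected gene are skipped.

## Synthetic data generator

The generator emulates the inputs of the pig domestication comparison,
not its biology. Defaults, and why:

* **Genome** — the 18 pig autosome lengths scaled by 0.02 (~45 Mb
  total). Keeping the true relative lengths (chr1 longest, chr18
  shortest) lets the per-chromosome density and length-correlation code
  run against a realistically shaped genome at desk scale.
* **Design** — 24 + 6 samples, matching the study's unbalanced
  domestic/wild split.
* **Planted regions** — 500 shared background regions (carrier
  frequency 0.5 in both populations, copy states {1, 3}) and 20
  differentiated regions (carrier frequencies 0.9 vs 0.1, copy states
  {0, 4}). Shared and differentiated regions carry different copy-state
  pools because the selected regions in such comparisons behave like
  near-fixed strong events while the background is dominated by
  heterozygous single-copy changes; one shared pool could not express
  that. Regions are 3–12 kb, placed non-overlapping proportionally to
  chromosome length with a guard gap wider than twice the boundary
  jitter, so jittered calls can never bridge two planted regions.
* **Noise** — multiplicative lognormal RD noise (σ = 0.05, the
  natural noise model for a depth ratio), endpoint jitter up to
  ±200 bp, carrier e-values U(0, 0.005).
* **False positives** — 4.0 calls per sample per Mb, 0.6–4 kb long,
  with RD drawn from U(0.6, 0.8) ∪ U(1.25, 1.4) to straddle the filter
  thresholds and 30% of e-values above 0.01, so every filter rule
  rejects something observable. The rate is set so the final region
  count is ≈ 2100: a top-1% selection then has rank capacity (~21
  regions) for the 20 planted differentiated regions. This coupling is
  structural — percentile selection can only recover a planted class
  that is no larger than the percentile — so the two defaults must move
  together.

Problem sizes throughout (region counts, ten-seed averaging in the
recovery checks, 1000-replicate enrichment null) are chosen so the full
suite exercises every stage at statistically meaningful scale while
remaining a desk-scale computation.

What the generator does **not** model: real read-depth profiles (GC
bias, mappability, segmentation artifacts), CNVnator's caller
internals, linkage between regions, demography within populations, sex
chromosomes, and overlap structure between planted regions. Passing
recovery tests therefore shows the *pipeline arithmetic* — filtering,
merging, copy-number aggregation, VST ranking — recovers planted
differentiation under calibrated noise; it says nothing about caller
accuracy on real alignments.

## Numerical and degenerate-input choices

* Median CNVR length for an even count is the mean of the two central
  values; chromosomes with no CNVRs report density/coverage 0, lengths
  0, and an `empty` flag rather than NaN-poisoning downstream tables.
* DUP/DEL ratio excludes mixed (BOTH) regions and is NaN when there are
  no deletions.
* Pearson correlations require ≥ 3 chromosomes and return NaN under
  zero variance.
* Floats in output tables are rendered at 6 significant digits; the
  simulator's round trip through its own files is exact at that
  precision and byte-identical under a fixed seed.

## Known limitations

* The copy-number estimator is call-based; samples whose variant allele
  was missed by the caller are imputed diploid, which biases VST
  downward for low-frequency regions. The full-scale remedy
  (re-genotyping depth over every region) needs the alignments, which
  are out of scope here.
* VST is a two-population statistic by construction; multi-population
  designs need a different decomposition.
* Enrichment treats terms independently (no GO DAG propagation, no
  pathway topology).
* UPGMA assumes a molecular-clock-like distance structure; it is used
  here as a deterministic clustering display, not a phylogeny estimate.
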