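# cnvpop

Copy-number-variation population analysis for two-population
resequencing studies: filter read-depth CNV calls, merge them into
copy-number-variable regions (CNVRs), score each region with the VST
differentiation statistic, select the top-percentile regions, and
annotate them against gene and QTL intervals.

The pipeline follows the design used to compare Chinese indigenous
domestic pigs with Asian wild boars: an unbalanced two-population
design (24 + 6 samples), CNVnator-style per-sample calls on the 18 pig
autosomes, and percentile-based selection of the most differentiated
regions as candidate domestication signatures. Everything is driven by
plain-text tables, so any CNVnator-dialect call set with a sample
manifest can be analysed the same way.

## The statistic at the core

For one CNVR with estimated copy numbers pooled across both
populations,

```
VST = (V_total − (V_pop1·N_pop1 + V_pop2·N_pop2) / N_total) / V_total
```

where `V_total` is the variance of the pooled copy numbers, `V_pop1`
and `V_pop2` are the within-population variances, and `N_pop1`,
`N_pop2`, `N_total` the sample counts. Like FST, it is the fraction of
copy-number variance explained by the population split: 0 when the
populations are indistinguishable, 1 when each population is internally
uniform but the two differ. Variances use the denominator-`N`
convention, under which the weighted within-group term is exactly the
pooled within-group sum of squares over `N_total` and VST stays in
[0, 1]. Regions with no copy-number variation at all are assigned
VST = 0 and flagged degenerate.

Upstream, calls are kept only if e-value < 0.01, deletion RD < 0.7 or
duplication RD > 1.3, and length > 1 kb; filtered calls from different
samples sharing ≥ 1 bp are merged transitively into CNVRs. Downstream,
the top 10% / top 1% of the VST distribution are selected by
nearest-rank percentile (ties included) and intersected with gene and
QTL interval files; overlapping genes feed a hypergeometric
term-enrichment test with Benjamini–Hochberg correction.

## Worked example

The package ships a synthetic-data generator that emulates the study
design: scaled pig autosomes (~45 Mb), 24 + 6 samples, 500 shared
background regions, 20 population-differentiated regions (carrier
frequencies 0.9 vs 0.1), read-depth noise, boundary jitter and
false-positive calls straddling the filter thresholds. The numbered
scripts under `analysis/` run the whole pipeline on it:

```
python analysis/01_simulate.py --seed 1
python analysis/02_filter_calls.py
python analysis/03_build_cnvrs.py
python analysis/04_differentiation.py
python analysis/05_annotate.py
python analysis/06_reported_table_stats.py
```

Output from that exact sequence:

```
calls emitted: 13408
planted regions: 520 (20 differentiated)
raw calls: 13408
kept: 9902 (rejected by e-value 1627, RD 2262, length 679)
view all: 2094 CNVRs
view AQ: 1802 CNVRs
view SS: 851 CNVRs
VST over 2094 CNVRs; thresholds: top-10% >= 0.138, top-1% >= 0.266
selected: 215 (top 10%), 21 (top 1%)
top-1% recovery of planted differentiated regions: sensitivity 1.00, FDR 0.05
PCA variance explained: PC1 8.50%, PC2 4.46%
selected CNVRs: 21; gene overlaps: 23; QTL overlaps: 3
most enriched term: T_signal (k=20/26, p=3.14e-20, q=5.02e-19)
```

Reading this: of 13,408 simulated calls, 9,902 survive the four
high-confidence filters and merge into 2,094 CNVRs. The top-1% VST
selection (21 regions) recovers all 20 planted differentiated regions
with one false discovery, the first principal component separates the
two populations, and the term planted on the differentiated-region
genes dominates the enrichment test — the pipeline finds exactly the
signal that was put in.

`06_reported_table_stats.py` recomputes the summary arithmetic of the
published per-autosome CNVR count table shipped with the package
(10,429 / 10,279 / 4,479 CNVRs; genome densities 4.60 / 4.54 / 1.98 per
Mb; DUP/DEL ratio 1.15; length–count Pearson r 0.917).

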