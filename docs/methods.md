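# Methods

## Coordinates and signal

All coordinates are 0-based half-open (BED convention) on every code path;
dialects that differ are converted at I/O boundaries. A DHS site's *center*
is `floor((start + end) / 2)`. Strand is carried but ignored by all overlap
and signal arithmetic; only TSS derivation is strand-aware. Signal tracks
are piecewise-constant runs (bedGraph semantics); positions outside any run
have value zero, and aggregation (sum / mean / max over per-base values)
treats uncovered bases as zeros. Overlap between half-open intervals
requires at least one shared base (`a.start < b.end and b.start < a.end`);
nearest-coordinate ties break toward the smaller coordinate, then
lexicographic identifier, so every query is deterministic.

### PCR-artifact filter

DNase-seq read 5′-end stacks are filtered by a centered-window rule: for a
position with count *c*, if *c* exceeds 70 % of the total 5′-end count in
the 31-bp window centered there (strict inequality: exactly 70 % is kept),
all reads at that position are removed. Every window is evaluated against
the original counts before any removal is applied, making the result
order-independent; the filter is idempotent whenever no position newly
exceeds the threshold after removal, and with `max_frac = 1.0` it is the
identity. The window is centered rather than sliding-anchored; this is a
configurable choice.

## Differential accessibility model

Counts are modeled as `k_ij ~ NB(mu_i * s_j, alpha)` with
`var = mu + alpha mu^2`. Size factors `s_j` use the median-of-ratios
method over sites with all-positive counts (an error recommends a
pseudo-reference fallback when no such site exists). The test statistic is
the Wald ratio of

```
lfc_i = log2(mean_T,i + 0.5) - log2(mean_C,i + 0.5)
```

(normalized condition means, pseudo-count 0.5 for stability at low counts)
to a delta-method standard error with
`var(mean) = (mu * avg(1/s_j) + alpha mu^2) / n`, referenced to a two-sided
normal; BH adjustment runs over all sites.

**Dispersion.** Per-site method-of-moments estimates
`(var - shot noise) / mean^2` from 2–3 replicates are far too noisy to plug
into a Wald SE directly — doing so produces a Welch-like statistic whose
normal reference is anti-conservative (empirical type-I error ≈ 0.12 at
n = 3). The default therefore shrinks completely to a shared dispersion:
the across-site **mean** of the per-site estimates restricted to sites with
normalized mean > 5, floored at 0.01. The mean, not the median, is used
because the per-site estimator's distribution is right-skewed and its
median sits well below the shared dispersion, which again inflates type-I
error. With the shared estimate the null p < 0.05 fraction is ≈ 0.05 at
2000 sites and 3 vs 3 replicates. `dispersion_pooling="per_site"` retains
the raw estimates for data where a shared dispersion is implausible. This
stage is deliberately a transparent stand-in for DESeq2: no dispersion
trend, no LFC shrinkage, no independent filtering.

**Status labels.** `opened`/`closed` require FDR < 0.05 with the matching
sign. `stable` — used downstream as the control class — requires a
two-sided guard band (FDR > 0.5 **and** |lfc| < 0.25) so near-significant
sites do not contaminate the controls; everything in between is
`ambiguous` and excluded. All-zero sites get p = 1 and `stable`. Promoter
classification is strict: center-to-TSS distance < 2000 bp (measured from
the site center; both the threshold and anchor are configurable).

## Expression association

Each site maps to the single gene whose TSS is nearest its center
(TSS rather than gene-body edge, matching the promoter definition;
configurable). Genes are stratified by counts of nearest opened/closed
sites (≥ 1 and ≥ 2, each gene once per stratum, deduplicated to one
fold-change per gene) and compared against all expressed genes — the gene
universe is the expression table. The Mann–Whitney test is two-sided; for
n₁ + n₂ ≤ 12 the p-value is an exhaustive permutation enumeration of the
U statistic (exact in the presence of ties, two-sided by distance from the
permutation mean n₁n₂/2), otherwise the tie-corrected normal
approximation. Cumulative curves are empirical CDFs on the sorted union of
observed fold-changes. Gene-set overlap percentages are
`100 |A∩B| / |A|` reported to one decimal.

## Occupancy and profiles

Overlap proportions count class members overlapped by ≥ 1 peak base.
Peak-level signal for correlation is the summed per-base depth-normalized
(reads-per-million) value over the peak; correlation is Spearman with
average-rank ties and no background subtraction. Metaprofiles use the mean
per-base signal per bin (± 1 kb, 20-bp bins by default); SEM is computed
across sites per bin (replicate-level SEM requires replicate tracks and is
available by supplying them); sites whose window a chromosome end would
truncate are dropped and counted.

## Matched classification

Genic exclusion drops sites whose center is within 2 kb of a TSS or whose
interval overlaps any exon. Matching covariates are `log1p` summed DNase
signal in center ± 200 bp and focal-TF signal in center ± 150 bp,
standardized over the pooled opened + stable set. "Close to equal" is
implemented as greedy 1:1 nearest-neighbor matching without replacement in
that 2-D space: opened sites are processed in seeded random order, each
taking its Euclidean-nearest unused stable site within a caliper of
0.25 SD, else dropped (drop count reported). Greedy seeded order keeps the
procedure simple and faithful to random selection; optimal bipartite
matching was considered and left out as unnecessary for balance
(post-match standardized mean differences land well below 0.1).

Features: for TF assays, the maximum over sliding 200-bp windows
(100-bp step, edge-anchored so all windows lie inside center ± 300 bp) of
the window's **mean** per-base pileup — mean-per-window is more
noise-robust than max-of-maxes and the max-over-windows retains locality;
chromatin-modifier assays use the same statistic over center ± 700 bp;
histone marks use the total summed signal in center ± 700 bp. Signals are
used as provided (tree ensembles are monotone-invariant, so no log
transform).

The classifier is a random forest with 500 trees and mtry 10, evaluated
over 10 stratified 75/25 train/test splits; "opened" is the positive class
for sensitivity. Importance is the Gini (mean decrease in impurity) per
feature averaged over runs, with permutation importance (mean decrease in
held-out accuracy over 3 column shuffles) as tie-breaker, and per-run rank
variance as a stability column. All stochastic steps draw named substreams
of one master seed.

## Synthetic data generator

The generator emulates the study conditions: 12,000 DHS sites (600 bp) on
five 8-Mb chromosomes with 1200 genes; 5 % opened + 5 % closed sites
(~10 % differential) at |lfc| = 2; NB dispersion 0.05; log-normal baseline
means (log-mean 4.6 ≈ 100 reads, log-sd 1.0); 3 replicates per condition
with size factors uniform in [0.7, 1.4]; 20 % of sites promoter-proximal
(placed < 2 kb from a TSS; the rest ≥ 2 kb from every TSS and clear of
exons, so exclusion filters have exact truth); 40 % of sites TF-bound.
Tracks are triangular bumps (half-width 500 bp, 50-bp rendering
resolution) on a 0.1 background; a shared per-site activity factor couples
DNase and TF amplitudes (Spearman ≈ 0.65 at peaks, as accessibility and
occupancy co-vary in real data), and opened sites carry a 2× amplitude
confound on both matching covariates so matching has real work to do. The
poised mark is 3× enriched at opened ∧ bound sites, active marks/modifiers
3× at stable ∧ bound sites, and three neutral assays per feature class act
as negative controls for importance ranking. Expression effects are
`Normal(±1, 0.5)` increments per direction-matched nearest site with
coupling probability 0.7 by default (1.0 in recovery checks), additive
over sites — encoding the observed additivity of multi-site effects as a
generative assumption. Under the defaults the matched classification set
lands near 930 rows, the scale of the study's matched analysis.

Randomness: one master seed; each generator stage derives an independent
substream via `SeedSequence([seed, crc32(stage_name)])`, so adding a stage
never shifts another's draws, and output is identical across platforms.

**What the generator does not emulate:** read-level data (no FASTQ,
fragment-length, mappability, or GC structure), spatial autocorrelation of
background signal, correlated replicates, overdispersion trends in the
mean, multi-TF co-binding structure, or distance-decaying enhancer–gene
regulation (coupling is nearest-gene only). Passing tests therefore
demonstrate procedure correctness — calibration, recovery of planted
structure, balance, importance ranking — not biological conclusions about
real chromatin.

## Problem sizes and numerical choices

Calibration and recovery checks run at 2000 sites with 3 vs 3 replicates;
association recovery uses 20 seeds at 2000 sites / 300 genes; the
end-to-end run uses the full default configuration. These sizes give
binomial tolerances comfortably tighter than the assertion bands while
keeping any single check under a couple of minutes. Ties and degenerate
inputs: all-zero count rows get p = 1; empty strata are reported with NaN
statistics rather than errors; empty site classes are flagged; equal-value
singleton comparisons return p = 1 on the exact path. Dispersion floor
0.01 and pseudo-count 0.5 guard low-count behavior and are configurable.
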