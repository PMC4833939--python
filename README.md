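# dhsdelta

Analysis toolkit for studying how histone deacetylase inhibitors (HDACi)
remodel chromatin accessibility. HDACi treatment of leukemia cells changes
DNase I hypersensitivity at a specific minority of regulatory sites rather
than genome-wide; this package implements the computational pipeline for
characterizing those changes and for asking which chromatin features mark the
"poised" transcription-factor-bound sites that respond:

1. **Differential accessibility** — negative-binomial Wald tests on DHS
   read-count matrices (median-of-ratios normalization, BH-adjusted FDR),
   classifying sites as *opened*, *closed*, *stable*, or *ambiguous*, with
   promoter (< 2 kb from a TSS) vs distal annotation.
2. **Expression association** — each DHS site is assigned to its nearest
   gene; genes nearest ≥ 1 or ≥ 2 direction-matched differential sites are
   compared against all expressed genes with Mann–Whitney rank-sum tests and
   cumulative fold-change curves.
3. **Occupancy and profiles** — TF-peak overlap proportions per site class,
   depth-normalized Spearman correlation of signals at peaks, and mean
   signal metaprofiles ± 1 kb around site centers.
4. **Poised-site classification** — after excluding genic sites, each opened
   site is paired with a stable control of close-to-equal baseline DNase and
   TF signal (greedy seeded nearest-neighbor matching in standardized
   covariate space, caliper 0.25 SD); windowed signal features per assay
   (max of 200-bp window means within ± 300 bp for TFs, ± 700 bp for
   chromatin modifiers; total signal in ± 700 bp for histone marks) feed a
   random forest (500 trees, mtry 10, ten stratified 75/25 splits) ranked by
   Gini importance.
5. **Synthetic data** — a fully seeded generator plants every structure the
   pipeline must recover: NB replicate counts with ~10 % differential sites,
   peak-shaped pileup tracks whose enrichment differs by site class
   (a repressive "poised" mark at opened TF-bound sites, active marks at
   stable bound sites, neutral control assays), TF peak sets, and expression
   fold-changes coupled additively to nearby site opening.

The statistical model for counts is `k_ij ~ NB(mu_i * s_j, alpha)` with
`var = mu + alpha * mu^2`; the Wald statistic tests
`log2((mean_T + 0.5) / (mean_C + 0.5))` with a delta-method standard error
and a shared method-of-moments dispersion. See `docs/methods.md` for the
full model, parameter defaults, and design choices.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (large intermediate files go to `scratch/`, summary tables to
`results/`):

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_differential.py
python analysis/03_expression_association.py
python analysis/04_occupancy_profiles.py
python analysis/05_poised_classifier.py --seed 1
```

With seed 1 the generator plants 600 opened, 600 closed, and 10,800 stable
sites among 12,000. Stage 2 prints

```
status
stable       6474
ambiguous    4280
opened        624
closed        622
realized FDR 0.043, sensitivity 0.994
```

— the NB test recovers nearly all planted differential sites while keeping
the realized false discovery rate under the nominal 0.05. Stage 3 shows the
planted expression coupling: genes nearest ≥ 1 opened site shift up
(median shift +0.60, Mann–Whitney p ≈ 8 × 10⁻²⁴) and genes nearest ≥ 2
opened sites shift further (+1.00), the additive-effect signature. Stage 5
matches 463 opened/stable pairs (926 rows; standardized mean difference on
the DNase and TF covariates drops from 1.07/0.73 before matching to < 0.01
after), then reports

```
      accuracy  sensitivity  specificity
mean     0.707        0.708        0.706
```

with the three planted informative assays (`active_modifier`,
`active_mark`, `poised_mark`) ranked 1–3 by Gini importance and every
neutral control assay below them — the classifier finds exactly the marks
the generator made predictive, at an accuracy far above the 0.5 chance
level of the matched design.

## Layout

- `src/dhsdelta/` — the library: `intervals`, `signal`, `reads` (PCR-artifact
  filter), `simulate`, `differential`, `association`, `profiles`,
  `classifier`.
- `analysis/` — thin numbered drivers over the library.
- `tests/` — unit, property, and end-to-end suites with brute-force oracles.
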