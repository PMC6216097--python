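# usvqtl

Quantitative genetics of mouse infant ultrasonic vocalization (USV) traits.

When an isolated mouse pup calls, the number, duration, peak frequency and
peak amplitude of its calls — and its repertoire over ten call categories —
vary strongly between inbred strains. This package implements the analysis
chain used to dissect that variation in a C57BL/6J (B) × DBA/2J (D) diallel
cross and in the BXD recombinant inbred (RI) family, for researchers mapping
behavioral traits in inbred mouse panels:

* **Variance partition and heritability.** Sequential (type-I) ANOVA over
  strain, litter, sex and weight; broad-sense H² = SS_strain/SS_total; and
  the heritability of strain means for RI panels,

  HRIx̄² = V_a / (V_a + V_e / n),

  where V_a is the between-strain variance component, V_e the within-strain
  variance, and n the replicates per line. Confidence intervals come from
  recomputing the estimator on many random 95% subsets of the pups; per-day
  estimates are combined by inverse-squared-SE weighting.
* **Diallel parent-of-origin tests.** Reciprocal F1 hybrids (B6D2F1 vs
  D2B6F1) share a nuclear genome, so a rank test between them isolates
  maternal-environment and imprinting effects. Kruskal–Wallis, pairwise
  Wilcoxon, and Tukey HSD group comparisons; mean-of-ratios call-type
  percentage profiles; serial-section volume estimation.
* **QTL mapping of strain means.** Winsorization of outlying strain means
  (|z| > 2.5), Haley–Knott regression on expected allele dosages at markers
  and pseudomarkers, LRS = N·ln(RSS₀/RSS₁) with LOD = LRS/4.61, genome-wide
  significant/suggestive thresholds from 5,000 permutations (95th/37th
  percentile of the max-LRS null), 1.5-LOD-drop support intervals, 2,000-
  resample bootstrap of the peak location, and an EMMA-style kinship mixed
  model as a relatedness-robust confirmation scan.
* **Candidate-gene triage.** Genes in a support interval carrying coding
  variants (nsSNPs/InDels), tiered by membership in three evidence lists
  (cis-eQTL, trait-correlated expression, prior phenotype).
* **Synthetic data.** RI genotype mosaics with sib-mating-expanded
  recombination R = 4r/(1+6r), pup-level phenotypes with
  strain/QTL/litter/maternal/day/residual variance components, diallel
  families with reciprocal F1s, and multinomial call-type counts — so every
  stage is testable without raw recordings.

## Layout

The library lives under `src/usvqtl/` (`io`, `simulate`, `heritability`,
`diallel`, `scan`, `triage`); `analysis/01…07_*.py` are narrative drivers
that run the pipeline end to end and write tables under `results/` (bulky
simulated inputs go to `scratch/`). A thin CLI is included:
`usvqtl simulate|herit|diallel|scan|triage --help`.

## Worked example

`analysis/01_simulate_panel.py` simulates a 41-strain panel (1,007 markers)
with a QTL planted at marker c8m020 (58.8 Mb on chr8) carrying 60% of the
genetic variance of peak amplitude. `analysis/04_qtl_scan.py` then maps the
day-7 strain means and prints:

```
winsorized: nothing (no |z| > 2.5)
thresholds (LRS): significant 17.31, suggestive 10.36
peak: chr8 c8m016+1cM @ 49.5 Mb, LOD 2.88 (suggestive); 1.5-LOD interval 41.1-60.7 Mb
peak: chr8 c8m019+1cM @ 57.9 Mb, LOD 3.01 (suggestive); 1.5-LOD interval 41.1-60.7 Mb
bootstrap modal position: c8m019+1cM (138/2000 resamples)
mixed-model confirmation: peak at c8m019+1cM (plain scan peak c8m019+1cM), LOD 3.01 vs 3.01
```

The scan recovers the planted locus: the strongest position sits one marker
from the causal one, the 1.5-LOD interval (41.1–60.7 Mb) contains it, the
bootstrap mode coincides with the peak, and the kinship-adjusted scan
agrees with the plain one. The LRS thresholds are the 95th (significant)
and 37th (suggestive) percentiles of the permutation null.

`analysis/05_candidate_triage.py` ranks the shipped gene tables for the two
published QTL intervals (chr2 179.5–180.8 Mb; chr8 3.5–16.7 Mb):

```
chr2 179.5-180.8 Mb: 17 coding-variant genes, 17 with >= 1 evidence line, top tier empty
chr8 3.5-16.7 Mb: 13 coding-variant genes, 13 with >= 1 evidence line, top tier ['Arhgef10', 'Csmd1', 'Dlgap2']
```

On chr2, no gene appears in all three evidence lists (17 appear in at least
one); on chr8, exactly *Dlgap2*, *Arhgef10* and *Csmd1* carry all three
lines of evidence and are the strongest candidates for peak amplitude.

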