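# Methods

This note documents the models, estimators and numerical conventions the
package implements, the design choices made where the analysis left the
design open, and what the synthetic-data generator does and does not
emulate.

## Heritability estimators

**Variance partition.** `variance_partition` fits an ordinary least-squares
model and reports sequential (type-I) sums of squares in the caller's factor
order, the R-style convention for these analyses. Categorical factors
(strain, litter, sex) are coded as treatment contrasts; numeric columns
(weight, day) enter as covariates. Litters are nested in strains: when both
factors are requested, litter labels are re-coded within strain so the
nested term gets its correct degrees of freedom. Fractions are of the total
SS and always sum to 1 including the residual. Zero total variance and
single-level factors are errors, not silent degenerate fits.

**Broad-sense H².** `broad_h2` is the strain-only partition,
H² = SS_strain/SS_total, computed on per-pup values (pups averaged over
their recording days unless a single day is requested). For fully inbred
strains the between-strain component carries the whole genotypic value, so
this is a broad-sense estimate. The variance components are extracted by
the balanced-design moment estimator,

    Va = (MS_strain − MS_within) / n̄   (floored at 0),   Ve = MS_within,

with n̄ the mean per-strain replicate count — a deliberate, simple
convention for mildly unbalanced data; REML is out of scope.

Note that H² as an SS ratio has a positive finite-sample bias of roughly
(1 − H²-ish) order at realistic panel sizes: with 41 strains × 8 pups the
expectation of SS_strain/SS_total at a true strain fraction f is
(s−1)(n f + 1 − f) / [(s−1)(n f + 1 − f) + s(n−1)(1 − f)], e.g. ≈ 0.47 at
f = 0.4 but ≈ 0.82 at f = 0.8. Parameter-recovery tests therefore target
the upper-heritability regime the measured traits actually occupy
(duration/amplitude), where the bias is inside the ±0.05 recovery band. The
HRIx̄² moment estimator does not share this bias (Va and Ve are unbiased),
and its recovery is tested at a configured HRIx̄² of 0.8.

**Heritability of strain means.** `hri2` implements
HRIx̄² = Va/(Va + Ve/n): resampling an inbred genome n times shrinks the
environmental term by 1/n, which is what governs power to map strain means.
It is monotone in n and reduces to the individual-level ratio at n = 1.

**Subsample CIs.** `subsample_ci` re-evaluates an arbitrary statistic on
`iterations` uniform without-replacement subsets of ⌊keep_fraction·N⌋
pup-day records (default 95%) and reports the 2.5th/97.5th percentiles of
the resampled values. The source analysis describes recording "the 95th
percentile" as the 95% CI while tabulating both a max and a min column; we
return explicit two-sided percentiles and label them as such. Default
iteration counts in the drivers are 1,000 (the study used 100,000; the
percentile estimates stabilize far earlier and the loop is embarrassingly
parallel if more are wanted).

**Day averaging.** `combine_across_days` is the inverse-squared-SE weighted
mean, Σ(hᵢ/SEᵢ²)/Σ(1/SEᵢ²); entries with missing SEs are dropped. It takes
any list, so the caller may combine the three daily estimates with or
without the 3-day-average trait.

**Diagnostics.** `trait_diagnostics` returns z-scores, Blom-position
normal-probability coordinates, and the largest successive gap between
sorted z-scores. The gap is a crude bimodality indicator: a balanced
mixture of normals at ±2 SD produces gaps beyond the 95th percentile of
matched unimodal simulations (checked by simulation in the tests); a
bimodal strain-mean distribution is the classic signature of a segregating
major-effect locus.

## Diallel analysis

Group comparisons report a Kruskal–Wallis overall test, pairwise Wilcoxon
rank-sum p-values deliberately left unadjusted (matching the figure-level
convention of the source analysis, which states no correction), and Tukey
HSD as the multiplicity-adjusted parametric alternative.

`parent_of_origin_test` compares the reciprocal F1 groups by a two-sided
Mann–Whitney test, optionally restricted to females (which removes any
Y-chromosome contribution), and reports the sign of the B6-dam-minus-D2-dam
difference. Because the reciprocals are genetically identical, rejection
indicates maternal environment or imprinting rather than inherited alleles;
the test itself cannot distinguish the two.

Call-type profiles are **means of per-subject ratios**, not ratios of
pooled sums: each subject's ten counts are normalized by its own total
before averaging, so prolific callers do not dominate the group profile.
Subjects with zero calls are excluded with a warning (or an error under
`strict=True`); the convention is ours, the source being silent.

`section_volume` is Σ areaᵢ × spacing (mm² × mm), the serial-section
estimator used for laryngeal cartilage volumes.

## QTL mapping

**Winsorization.** Strain means with |z| > 2.5 (z from the full set's mean
and SD, ddof = 1) are replaced by the nearest retained value on the same
side, and every change is logged ("STRAIN from old to new"). The rule is
two-sided although the source text writes "> +2.5 z", because its own
worked example raises a low value; the replacement rule (nearest retained
value) is our explicit reading of "shifting values so as to approximate a
more normal distribution". Winsorization never reorders retained values.

**Dosages.** B → −1, D → +1 at genotyped markers; heterozygous/unknown
calls are treated as missing and mean-imputed per position. Pseudomarkers
(default 1 cM grid) take the conditional expectation of the dosage given
the flanking markers under a two-state chain whose flip probabilities are
the sib-mating-expanded recombination fractions R = 4r/(1+6r), with r from
Haldane's map function; the chain is composed (R_total = R_L + R_R −
2R_L·R_R) so the conditional probabilities normalize exactly. Linear cM
interpolation is available via `method="interpolate"`. Under this model a
pseudomarker between concordant flanks has |dosage| slightly below 1
(double recombination has positive probability); the gap must shrink for
the dosage to approach ±1.

**Scan statistic.** Per position, strain means are regressed on dosage with
an intercept; LRS = N·ln(RSS₀/RSS₁) and LOD = LRS/4.61 (the stored
constant; the contract LOD = LRS/4.61 holds at every emitted position).
The additive coefficient is the regression slope under ±1 coding, i.e.
half the D-minus-B class difference. Constant-dosage columns get LRS = 0.

**Permutation thresholds.** The strain-mean vector is permuted across
strains (the analysis maps strain means; individual-level permutation is
deliberately not offered) and the genome-wide maximum LRS recorded per
permutation. Significant = 95th percentile (genome-wide p < 0.05);
suggestive = 37th percentile, the genome-wide p < 0.63 convention of
roughly one false QTL per scan. Defaults: 5,000 permutations.

**Support intervals.** 1.5-LOD drop: from the peak, walk over contiguous
positions on its chromosome while LOD ≥ peak − 1.5; edges are reported in
Mb and truncated at chromosome ends.

**Bootstrap.** Strains are resampled with replacement (default 2,000
times), the scan recomputed, and the genome-wide peak position tallied;
ties go to the lowest coordinate. The histogram's concentration is a
stability read-out for the peak location.

**Kinship and mixed model.** The kinship matrix is the GEMMA-style centered
genotype cross-product, K = ZZᵀ/m over mean-imputed, column-centered
dosages — symmetric PSD by construction (the source names the tool, not the
formula, so the formula is our choice). `kinship_lmm_scan` fits
y = xβ + u + e with cov(u) ∝ K by spectral decomposition: the variance
ratio δ = Ve/Vg is estimated once under the null by a bounded 1-D search on
the restricted likelihood, then every position is tested by a GLS
likelihood ratio on the rotated data (the "population parameters previously
determined" approximation); `per_marker_opt=True` re-optimizes δ per
position. Non-PSD or asymmetric K is rejected.

**Peak report.** Contiguous supra-suggestive runs each yield one peak;
a dip below the suggestive line splits a region into sibling peaks. For
sibling peaks on one chromosome the report counts strains with opposite
parental alleles at the two peak markers (nearest genotyped marker if the
peak is a pseudomarker) — many discordant strains argue for two distinct
QTLs — and flags overlapping 1.5-LOD intervals, which argue that one locus
may suffice. Both readings are reported; the report does not decide.

## Candidate triage

`interval_candidates` keeps genes overlapping the support interval (any
overlap, closed endpoints — stated explicitly for testability) on the given
chromosome, optionally requiring a coding variant (nsSNP/InDel flag).
`evidence_rank` tiers genes by how many of the three curated evidence flags
are set; the evidence flags are inputs curated upstream from expression and
phenotype databases, never recomputed. The shipped
`data/chr*_candidates_synthetic.tsv` tables encode the published evidence
lists for the chr2 and chr8 intervals; per-gene coordinates in those files
are synthetic placements inside the intervals (no per-gene coordinates are
published) and the files carry extra rows solely to exercise the filters.

## Synthetic data: what it emulates, and what it does not

Genotypes follow a per-chromosome two-state chain: first marker B/D with
probability ½, adjacent-marker discordance R = 4r/(1+6r) with Haldane r
from the cM gap — the standard model for RI lines fixed by sib mating. No
heterozygous or unknown calls are emitted by default (the reader handles
them); X/Y and mitochondrial inheritance are not modeled.

Phenotypes are Gaussian component sums: grand mean + QTL additive effects
(±a by allele, variance nested inside the strain-level fraction) +
polygenic strain deviate + litter deviate + maternal (dam) deviate + fixed
day shift + residual, each scaled so realized variance fractions match the
configuration in expectation. Defaults reflect the measured structure of
these traits: strain fraction 0.4, litter 0.3 (litter effects are large —
up to half the variance for amplitude), day shifts worth ~1% of variance
(age had small significant effects), no sex effect (none was detected in
the quantitative traits), 3 litters × 3 pups per strain (within the
reported 2-to-5-litters design), recording days 7/8/9. Within-pup
day-to-day correlation defaults to 0 with a `pup_repeatability` knob, the
source reporting no value. The diallel generator gives the reciprocal F1s
one shared genetic value by construction, dam-strain maternal deviations,
and a parent-of-origin deviation entering the reciprocals with opposite
signs, so E[B6D2F1 − D2B6F1] = (maternal_B6 − maternal_D2) + 2·POE; sexes
alternate within litters. Call-type counts are multinomial over the ten
categories.

None of this emulates acoustic reality: no waveform synthesis, no amplitude
clipping (real loud calls clip and no correction is specified, so none is
applied), no classifier noise in call categories, Gaussian rather than
count-valued traits. Passing tests therefore demonstrate that the
*estimators and calibrations* behave as claimed under the assumed variance
structure — not that real recordings satisfy that structure.

## Problem sizes, tolerances and numerics

* Default stylized genome: 19 autosomes × 53 markers at 1.5 cM (~1,007
  markers, ~78 cM per chromosome, Mb = 3 + 1.86·cM) — mouse-like marker
  density at the scale where the BXD scan operates.
* Calibration tests run 200-replicate batteries: permutation-threshold
  type-I error 5% ± 3% (significant) and 63% ± 7% (suggestive) with
  5,000 permutations each; 1.5-LOD interval coverage ≥ 80% for a QTL at
  40% of strain-mean variance; heritability recovery within ±0.05 at 41
  strains. Power properties use 300–1,000 replicates with 400–500
  permutations per replicate on a reduced 10 × 40-marker map; these sizes
  keep Monte-Carlo error well inside the asserted bands while the whole
  battery stays fast.
* The published "80% power at half the genetic variance when HRIx̄² ≈ 0.5"
  statements are not desk-reproducible: the threshold and replicate
  assumptions behind them live in unavailable supplementary material, and
  the two printed statements are not jointly consistent under a single
  simple threshold model. The power machinery therefore exposes the policy
  as a parameter (permutation-significant, permutation-suggestive, or
  pointwise χ²₁) and is validated by properties instead: exact type-I
  calibration at zero effect, monotonicity in effect size, and near-certain
  detection at full genetic variance and high heritability.
  (`analysis/06_power.py` prints the package's own power curve; under the
  permutation-significant policy it reaches ~0.8 power near a 0.75 variance
  share at HRIx̄² = 0.5 and near a 0.4 share at HRIx̄² = 0.9.)
* Numerics: r² is clipped at 1 − 1e-12 before LRS = −N·ln(1−r²);
  constant-dosage columns get LRS = 0; the LMM's δ search is bounded on
  ln δ ∈ [−10, 10]; negative moment estimates of Va floor at 0; quantiles
  use NumPy's default linear interpolation; all tie-breaks (peak location,
  bootstrap tallies) go to the lowest coordinate.
* Determinism: every stochastic routine takes a seed; the simulators accept
  ints or `SeedSequence` objects and derive sub-streams deterministically.

## Known limitations

* The moment/ANOVA estimators assume balanced-ish designs; severe imbalance
  shifts n̄ away from the effective replicate count.
* The diallel "full model" strain fraction is reported as `h2_full_model`
  without claiming additivity: with four genotype groups it conflates
  additive and dominance variance.
* The LMM's single null-fitted variance ratio is an approximation; exact
  per-marker optimization is available but slower.
* Pseudomarker dosages treat the RI chain as Markov between flanks, which
  is exact for the simulator and the standard approximation for real RI
  genomes.
* Winsorization assumes at least one retained value per side; a set where
  every value is flagged is rejected.
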