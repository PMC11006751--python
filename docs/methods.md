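# Methods

This note describes the statistical models and procedures implemented in
`e4screen`, the assumptions behind the synthetic family-cohort generator,
and the design choices made where the problem left the design open.

## 1. The screening procedure

### Genotype and variant QC

Per-genotype calls with GQ < 20 or DP < 10 are set to missing; thresholds
are inclusive and configurable (`qc.gq_min`, `qc.dp_min`). QC degrades
calls to missing rather than removing them, so downstream denominators
reflect genotyped individuals only. The operation is idempotent.

Variant-level filters keep sites with reference-population allele
frequency strictly below 1% and consequence class in {missense, LOF} by
default. A missing reference AF is treated as 0 (kept, with a warning):
a rare allele absent from reference panels should not be removed by the
rarity filter. Variant filters commute, and no operation alters
coordinates, alleles or sample identity. Multi-allelic VCF rows are split
at read time into biallelic records with per-alt dosages; half-calls
(`0/.`) are conservatively treated as missing. Left-alignment is not
attempted: inputs are generated or pre-normalized.

### Stratification

Samples are assigned to every stratum whose predicate they satisfy:

| stratum | ε4 dosage | diagnosis | age floor |
|---|---|---|---|
| elderly_healthy_hom | 2 | control | ≥ 70 |
| all_healthy_hom | 2 | control | — |
| hom_AD | 2 | AD | — |
| elderly_healthy_het | 1 | control | ≥ 80 |
| all_healthy_het | 1 | control | — |
| het_AD | 1 | AD | — |
| noncarrier | 0 | any | — |

ε2/ε4 genotypes count as dosage 1: the screen stratifies only by ε4
carriage. Ages are floored to whole years before comparison and the
thresholds are inclusive (a `strict_age` switch gives the strict reading);
control ages are ages at last examination, AD ages are ages at onset, and
AD strata carry no age floor. Stratum MAF is alt alleles over twice the
genotyped individuals; an ungenotyped stratum yields a missing (not zero)
MAF.

### The segregation cascade

Order of gates, applied per cohort by default:

1. **Non-carrier absence** — zero alt alleles among genotyped ε4
   non-carriers of any age or diagnosis.
2. **Elderly homozygote support** — carrier fraction (carriers /
   genotyped individuals, not allele frequency) in the elderly unaffected
   ε4/4 stratum at least `min_elderly_hom_carrier_fraction` (default 1%).
3. **Heterozygote support** — at least one carrier among elderly
   unaffected heterozygotes (qualitative support; on by default).
4. **Case absence** — absence from ε4-carrier AD cases, applied per
   `case_absence_mode`: `hard_all_e4_AD`, `hard_hom_AD_only` (default) or
   `rank_only`. Tiers: 1 = absent in all ε4-carrier AD cases, 2 = absent
   in ε4/4 AD cases only, 3 = otherwise.

Candidates are sorted by (tier, descending elderly-ε4/4 carrier fraction,
genomic coordinate); coordinate ties make the ordering reproducible. In
multi-cohort data the cascade runs independently per cohort and also
reports the intersection of the per-cohort candidate lists.

Case absence deserves a note. A truly protective allele with OR ≈ 0.29 is
reduced, not eliminated, among AD carriers, so in a cohort with a
realistically sized ε4/4 AD stratum it will appear in at least one AD
case with non-negligible probability. A hard absence filter therefore
trades sensitivity for specificity in a way that depends strongly on the
AD stratum size, and the recovery guarantees quoted below are measured
with `rank_only`, where case absence ranks rather than removes. The hard
modes remain available and are the stricter default for interactive use.

## 2. The synthetic family cohort

The generator emulates a multiplex late-onset AD family study: nuclear
families (two founders, 2–6 offspring), ε4-enriched APOE allele
frequencies, roughly one third of the sample affected, and sequencing
artifacts typical of ~30× whole-genome data.

* **APOE** — founder alleles drawn iid from (ε2, ε3, ε4) frequencies
  (0.05, 0.60, 0.35 by default; ε4 is strongly enriched in multiplex AD
  families relative to the general population).
* **Planted protective variant** — resides on ε4 haplotype backgrounds:
  each founder ε4 haplotype carries it with probability
  `protective_af / freq(ε4)`, so the unconditional allele frequency equals
  `protective_af` (0.008 by default, under the 1% rarity bound). It is
  transmitted together with APOE as one linked block. This is the
  generative counterpart of the screen's premise — a variant
  co-segregating with ε4 in families and hence absent from ε4
  non-carriers. An unlinked rare variant would, in any cohort with
  hundreds of non-carriers, almost surely be observed in one of them and
  be (correctly) rejected by gate 1, so a strictly unlinked "protective"
  locus cannot model the phenomenon the screen targets.
* **Background variants** — 200 unlinked neutral sites with allele
  frequencies log-uniform on [10⁻⁴, 9×10⁻³], in Hardy–Weinberg proportions
  among founders, Mendelian transmission independent across loci. These
  are the negatives the cascade must reject; their annotated reference AF
  equals their generating frequency.
* **Liability** — P(AD) = expit(logit(b_d) + k·ln(OR)·1[d ≥ 1]) with
  baseline risks b = (0.15, 0.35, 0.55) for ε4 dosage d = 0/1/2, k the
  protective dosage, OR = 0.29. Each protective allele multiplies disease
  odds by exactly OR among ε4 carriers and does nothing in non-carriers.
* **Ages** — AD cases receive an onset age Normal(μ_d + k·δ, σ) with
  μ = (78, 73, 68) years, δ = 3.37 y per allele, σ = 6 y; controls receive
  a censoring age uniform on [60, 95]. Ages are reals in years, floored to
  integers only when compared to stratum thresholds.
* **Sequencing quality** — DP ~ Poisson(30), GQ ~ round Normal(85, 10)
  clipped to [0, 99]; a `qc_fail_fraction` (default 2%) of calls is
  degraded below the QC thresholds (half via GQ, half via DP). Failures
  degrade rather than delete calls so the QC filter itself is exercised.
* **Randomness** — one root seed; per-family substreams keyed by family
  counter (`SeedSequence(seed, spawn_key=...)`), so outputs are
  byte-identical across runs and independent of iteration order.
* **Ascertainment** — an optional `min_affected_per_family` filter
  resamples a family until it has at least that many affected members;
  it is off by default so that founder genotypes remain exactly
  Hardy–Weinberg, which the analytic null-calibration checks rely on.

What the generator does **not** model: recombination (APOE and the planted
site are one block; background sites are fully unlinked), genotype
imputation error, pedigree loops, population stratification and
relatedness beyond the nuclear family, sex chromosomes, and site-level
(VQSR-style) filters. Passing tests on these cohorts therefore shows the
pipeline's logic and calibration are correct under clean Mendelian
transmission and known truth, not that the screen is robust to cryptic
relatedness or imputation artifacts in real data.

### What the simulation-based checks establish

* On 50 default cohorts (400 families, ≈ 2,450 individuals, ≈ 90 elderly
  unaffected ε4/4), the cascade recovers the planted variant in ≥ 95% of
  replicates in `rank_only` mode; a variant observed in even one ε4
  non-carrier is excluded deterministically. The dominant failure mode of
  recovery is the heterozygote-support gate: carriers cluster in a handful
  of founder families, so the elderly-heterozygote stratum occasionally
  holds none.
* On founders-only null cohorts (no protective effect), the candidate
  count over 100 replicates matches the analytic expectation
  Σ_v (1−p_v)^{2n_nc} · (1−(1−q_v)^{n_EHom}) · (1−(1−q_v)^{n_EHet}),
  q = 1−(1−p)², within three Poisson-binomial standard deviations. The
  analytic form requires unrelated individuals, which is why the check
  simulates founders only.
* Logistic regression of status on dosage in 50,000 simulated ε4/4
  individuals recovers ln(0.29) within 2 SE, and OLS of onset age on
  dosage in the cases recovers δ = 3.37 y within 2 SE. Both are 2-SE
  checks and so fail for ≈ 5% of seeds by construction.

## 3. Replication statistics

* **Carrier EAF** — 100·(carriers × copies)/(2·N); carriers are assumed
  single-copy in the rare-variant regime, which reproduces
  published-style effect-allele frequencies exactly from carrier counts.
* **2×2 odds ratio** — cross-product ratio with Wald CI and p on the log
  scale; 0.5 added to every cell iff any cell is zero
  (Haldane–Anscombe); an empty case or control margin is an error.
* **SE from a printed CI** — (ln hi − ln lo)/(2·z), z = 1.959964 for 95%.
  The fixed quantile makes CI round-trips bit-stable.
* **IVW meta-analysis** — fixed-effects pooling on the log-OR scale with
  weights se⁻²; Cochran's Q with k−1 df. The pooled estimate always lies
  within the range of the inputs and its SE never exceeds the smallest
  input SE. Meta-analysis operates on printed CIs (via SE recovery) when
  raw SEs are unavailable, since only CIs are typically published.
* **Logistic association** — ML logistic fit of status on allele dosage
  with caller-supplied covariates; without covariates the slope equals
  the closed-form 2×2 log-OR (tested to 6 decimals). Perfect separation
  is flagged and the CI reported as unbounded rather than fabricated.
* **Age-at-onset model** — OLS of onset age on dosage (+covariates),
  cases only, 95% CI. Covariate sets are generic: adjusted estimates
  depend on cohort-specific covariates and are deliberately not a
  reproduction target.

## 4. Morphometry statistics

Per-vessel tables (subject, genotype group, diameter ≤ 50 µm, marker
intensity in arbitrary fluorescence units; larger vessels are excluded
upstream) are analyzed with:

* **Welch ANOVA** (statsmodels, Satterthwaite df) and **Brown–Forsythe
  modified F** (variance-weighted denominator, adjusted df). With two
  groups Welch's F equals the squared Welch t.
* **BKY two-stage adaptive FDR** — stage 1 is BH at q′ = q/(1+q) giving
  r₁ rejections; if r₁ ∈ {0, m} that is the answer, otherwise stage 2 is
  BH at q′·m/(m−r₁). Adjusted values are BH step-up values scaled by
  (m−r₁)(1+q)/m, so `adjusted ≤ q` reproduces the rejection set in every
  branch. The implementation follows the definition directly and is
  cross-checked in tests against both a literal brute-force oracle and an
  independent library implementation.
* **Kruskal–Wallis / Dunn** — tie-corrected H; Dunn's pairwise z on
  mean ranks with the tie-corrected variance, Bonferroni-adjusted over
  the tested pairs (the procedure names no other adjustment). If all
  observations are identical, H = 0 and p = 1 by convention.
* **Diameter regressions** — unweighted least squares, linear or
  second-order polynomial; "robust second-order polynomial with no
  weighting" is implemented as plain OLS on (x, x²) since order-2 and
  unweighted are the only stated attributes. Adjusted
  R² = 1 − (1−R²)(n−1)/(n−k−1).
* **Percent change** — 100·(mean_test − mean_ref)/mean_ref; only relative
  quantities are contract-level for intensities.
* **Kolmogorov–Smirnov** — two-sided two-sample test (scipy).

Type-I calibration of the four group tests is verified over 1,000 null
replicates of 3 normal groups of n = 100 — the scale of per-vessel
datasets, where each genotype group holds hundreds of vessels. At much
smaller group sizes the χ² approximation used by Kruskal–Wallis is
mildly anticonservative; that is a property of the approximation, not of
the implementation.

## 5. Numerical conventions and degenerate inputs

* 95% normal quantile fixed at 1.959964 throughout.
* MAF of an ungenotyped stratum is missing, never 0.
* Cascade aborts with a diagnostic naming the stratum when a required
  stratum (non-carriers, elderly unaffected homozygotes, and elderly
  unaffected heterozygotes when het support is required) is empty.
* Zero-variance groups, constant regressors, empty samples and empty
  2×2 margins raise errors rather than returning NaNs.
* Sorting uses stable merge sort with genomic-coordinate tie-breaks.

## 6. Known limitations

* Frequencies and counts take genotyped individuals as denominators;
  published tables whose denominators are unstated can only be reproduced
  when the implied genotyped counts are supplied.
* The cascade does not model relatedness when counting carriers: a single
  large carrier family can satisfy the elderly-homozygote gate on its
  own. The screen's published form has the same property.
* Adjusted (covariate-conditional) odds ratios are not reproducible
  without the individual-level replication data; the package reproduces
  the unadjusted 2×2 layer and the meta-analysis of printed estimates.
* The simulator's linked planted variant makes gate 1 deterministic for
  the true positive; real screens face imperfect linkage and genotyping
  error, so real-data sensitivity will be lower than the simulated one.
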