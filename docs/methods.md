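# Methods

This note documents the statistical models implemented in `regassoc`, the
defaults and why they were chosen, what the synthetic-data machinery does
and does not emulate, and the package's known limitations.

## Cohort model and orientation

The central object is a samples × variants matrix of minor-allele dosages
(0/1/2, `nan` for a failed genotype) with a case/control phenotype vector
and per-variant annotations. "Minor" is anchored in the **control** sample:
on input, any column whose counted allele exceeds 50% frequency among
genotyped controls is flipped, with ties at exactly 0.5 left on the alt
allele. Control anchoring matches how resequencing studies define rarity
("MAF ≥ 2% in the controls") and makes every downstream count table
case-enrichment-oriented. Positions are 1-based; the genome build is
carried as metadata and never used in computation.

## QC

* **HWE**: the standard exact conditional test — condition on the observed
  minor-allele count, enumerate all heterozygote counts of matching
  parity, and sum the probabilities of configurations no more probable
  than the observed one. Computed in log space (log-gamma + logsumexp) so
  cohort-scale counts are stable; a property test checks exact agreement
  with a rational-arithmetic enumeration oracle for all cohorts of ≤ 30
  diploids. Default exclusion threshold `hwe_alpha = 0.05`, evaluated in
  the combined sample (an artifact screen, mirroring cohort-wide exclusion
  of a failing indel); a controls-only scope is available since the
  original tool's scope is not documented. Variants failing HWE are
  removed before *every* downstream stage.
* **Rarity**: common iff control MAF ≥ `rare_maf` (default 0.02,
  boundary inclusive, matching the "≥ 2%" convention).

## Single-variant tests

Allelic (chromosome-level) 2×2 tables — the study's denominators are
allele counts — with the two-sided Fisher exact p under the
probability-mass convention (`scipy.stats.fisher_exact`; all
hypergeometric outcomes with probability ≤ the observed outcome's, within
1e-7 relative tolerance). The odds ratio uses the Woolf log-OR interval,
`log OR ± 1.96·sqrt(Σ 1/cell)`; with any zero cell the Haldane 0.5
correction is applied to every cell (on by default — the study's CI method
is not stated, and Woolf+Haldane is the standard choice). With correction
disabled, a zero-cell OR is returned as `nan` rather than raised: an
undefined OR is an expected outcome for singletons.

## Haplotypes

* **EM phasing**: haplotype frequencies over a marker set (≤ 12 markers,
  full enumeration) are estimated by EM over all diplotypes compatible
  with each unphased genotype; missing sites are summed over. Uniform
  initialization over compatible haplotypes; convergence when the largest
  absolute frequency change is below `tol = 1e-6` (cap 1000 iterations
  with a warning); the log-likelihood is asserted non-decreasing at every
  iteration. Haplotypes below `prune_freq = 1e-5` are dropped and the
  posteriors renormalized. The per-individual output is the posterior
  diplotype distribution and the posterior-expected haplotype dosage
  (rows sum to 2).
* **LD and blocks**: D′ and r² come from the two-marker EM fit; the 90%
  interval on |D′| is read off the normalized likelihood curve over a
  101-point D′ grid with allele frequencies held at their estimates and
  the sign of D fixed. Blocks follow the confidence-interval rule: a pair
  is in strong LD when (CI low ≥ 0.70, CI high ≥ 0.98), shows strong
  recombination when CI high < 0.90, and a contiguous span qualifies when
  ≥ 95% of its informative pairs are in strong LD; overlapping candidates
  are resolved longest-first. The thresholds are the method's published
  values and are configurable, since the original tool's settings are not
  printed.
* **Association**: per reported haplotype (frequency ≥ `min_report_freq`,
  default 0.01 — rarer haplotypes are pooled into the implicit "rest"
  side), a haplotype-vs-rest × case-vs-control table of posterior-expected
  counts, 1-df Pearson χ² without continuity correction, OR from the same
  fractional table with Haldane fallback. With fully unambiguous phase
  this reduces exactly to the integer-count χ² (tested).
* **Empirical p**: family-wise, max-statistic — for each permutation of
  the phenotype labels the largest χ² across reported haplotypes is
  compared against each haplotype's observed χ²; p = (1 + exceedances) /
  (k + 1). Diplotype posteriors stay fixed at the pooled-EM fit: the
  pooled fit is label-independent, re-phasing per permutation would cost
  orders of magnitude more, and the permuted quantity (labels) remains
  exchangeable under the null. Default k = 100,000.

## Weighted-sum burden test

Rare variants are grouped as: 5′ regulatory (promoter ∪ 5′ UTR), all
coding (synonymous ∪ non-synonymous), non-synonymous, predicted
deleterious (non-synonymous ∩ {possibly, probably damaging}), 3′ UTR, and
all rare (every class including intron and downstream — the grouping that
reproduces the published 67/32 allele totals). The statistic is the
controls-weighted sum rank: variant weights `w_j = sqrt(n_j q_j (1−q_j))`
with `q_j = (m_jU + 1)/(2 n_jU + 2)` estimated from genotyped controls,
individual scores `γ_i = Σ_j d_ij / w_j`, and `x` the sum of case midranks.
The alternative is one-sided case enrichment. Significance is by phenotype
label permutation (default k = 10,000), re-estimating the weights inside
every permutation — faithful to the cited method — with a fixed-weights
fast path available. The plus-one estimator keeps p ≥ 1/(k+1).

**Missing data**: an ungenotyped individual is scored as carrying zero
minor alleles at that variant (`missing_policy="zero"`). For variants with
control MAF < 2% an ungenotyped individual is a non-carrier with ≥ 98%
probability, and this choice keeps the ranking carrier-driven. The
alternative, mean imputation (`missing_policy="mean"`), gives every
ungenotyped individual a small positive score that separates them from
true non-carriers; when case and control call rates differ — as they do in
the reconstructed cohort, whose printed case denominators are
systematically lower — the rank order is then dominated by who failed
genotyping rather than who carries variants, and every group's p collapses
toward the missingness signal. Zero-scoring is therefore the default.

## Multiple testing

Benjamini–Hochberg step-up q-values (`statsmodels`), computed over exactly
the family passed in (for the haplotype stage, the reported haplotypes of
a block); membership is never inferred. Sanity anchor: the published
haplotype family's two smallest q-values follow as 0.0011·7/1 = 0.0077 and
0.0106·7/2 = 0.037.

## Synthetic cohorts

`simulate_cohort` draws, per individual, two haplotypes independently from
a frequency pool (so common markers are in HWE and their LD comes solely
from the pool — no recombination or coalescent model), places rare
variants as heterozygous carriers (exact per-arm counts or per-individual
carrier probabilities), applies MCAR missingness per genotype, and can add
an excess-homozygosity variant parameterized by an inbreeding coefficient
(default MAF 0.3, F = 0.2, which the exact HWE test rejects essentially
always at n = 1113). Defaults are the emulated study's conditions: 716
cases, 397 controls, the published 7-haplotype pool over the 8 scaffold
markers, the printed per-variant rare carrier counts, and 2.7%
missingness (printed mean call rate 97.3%). The published pool frequencies
sum to 0.974; the default renormalizes them to 1 rather than inventing an
eighth haplotype. One master seed drives independent child streams for
haplotype draws, rare placement, missingness and the HWE violator.

Heterozygous-only rare carriers are an idealization (at MAF < 2%
homozygotes are negligible); the generator does not model sequencing
error, relatedness, or population structure, so passing tests say nothing
about robustness to those features of real data.

`reconstruct_paper_cohort` is deterministic (no RNG): rare carriers are
heterozygotes assigned to distinct individuals in sequence, missingness is
placed on non-carriers with per-variant rotation so that the genotyped
totals match the printed allele denominators, and common variants are
instantiated from the printed frequencies at full call rate with genotype
classes in Hardy–Weinberg proportions. Printed allele denominators are
frequently odd, which diploid counts cannot produce; the reconstruction
uses ⌈denominator/2⌉ genotyped individuals (denominators exact for even
printed values, +1 for odd). Because the denominators vary by variant and
the overlap of failed samples across variants is unknowable, missingness
is assigned independently per variant.

## Numerical choices

* Permutation machinery is vectorized in chunks of 2,000 label
  permutations; comparisons against observed statistics use a 1e-9
  absolute guard so float noise cannot break exact ties.
* EM monotonicity is enforced with a 1e-8 relative tolerance; the HWE
  observed-configuration comparison uses a 1e-12 log-space guard.
* All empirical p-values use the plus-one estimator.
* Midranks are used throughout rank computations; with no carriers at all
  the statistic degenerates to n_case(N+1)/2 exactly.

## Limitations

* **Printed-table inconsistencies.** Ten of the 38 printed rare-variant
  Fisher p-values disagree at the third decimal (by 0.001–0.002) with any
  standard two-sided Fisher computation from the printed allele counts of
  the same rows, and several printed denominators are odd — impossible for
  diploid allele counts. The published p-values evidently came from
  slightly different underlying counts than the published denominators.
  The corresponding acceptance test asserts the printed values and fails
  on exactly those rows; the remaining 28 rows reproduce to the printed
  precision.
* **Burden p-values under reconstruction.** With the documented
  reconstruction assumptions, the 5′ regulatory, predicted deleterious and
  3′ UTR group p-values land within ~0.01 of print, but the groups
  dominated by the two multi-carrier variants (all coding ≈ 0.73 vs
  printed 0.575; non-synonymous ≈ 0.65 vs 0.560; all rare ≈ 0.24 vs
  0.192) do not: the rank statistic depends on the joint per-individual
  carrier configuration (overlap of carriers across variants, possible
  homozygotes behind counts like "2 of 752", the joint missingness
  pattern), which marginal printed counts cannot pin down.
* The common-variant haplotype empirical p-values and ORs printed for the
  study (e.g. 0.0024, 0.0311, OR 3.70) require the original genotypes —
  only rounded frequencies are printed — and are covered qualitatively by
  property tests (integer-χ² equivalence under known phase, EM frequency
  recovery within ±0.01 at n = 2000, family-wise ≥ per-test asymptotic p)
  rather than by numeric reproduction.
* EM phasing enumerates all compatible diplotypes and is limited to 12
  markers; no partition-ligation or sampling-based phasing is provided.
* No covariate adjustment, no genotypic/dominant/recessive single-variant
  models, and no other burden tests (CAST, CMC, variable-threshold, SKAT).
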