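# Methods

This note documents the models, algorithms, numerical choices and defaults
behind `sevariant`, and what the synthetic-data tests do and do not
establish about real data.

All genomic coordinates in the package are 0-based half-open (BED
convention); the only 1-based surface is the POS column of written/read VCF,
converted at the boundary.

## Super-enhancer calling

Input is a set of signal-carrying peaks (e.g. H3K27ac ChIP-seq peak calls
with a per-peak signal level) and a TSS annotation.

1. **TSS exclusion.** Any peak overlapping any interval [TSS−w, TSS+w) is
   removed (default w = 2,500 bp). Overlap semantics, not midpoint or
   containment: a peak touching the half-open boundary is retained. Strand
   is ignored — the TSS is a point and the window symmetric. Peaks on
   chromosomes absent from the annotation are retained (there is no TSS
   near them) and counted in the log.
2. **Stitching.** Peaks whose gap (next.start − prev.end) is ≤ 12,500 bp are
   merged transitively per chromosome; overlapping peaks have gap ≤ 0 and
   always merge. A stitched region's signal is the **sum** of its
   constituent peak signals — no input/control subtraction, since the
   procedure is defined on peak calls alone.
3. **Threshold.** Regions are sorted ascending by total signal. With
   s = (y₍ₙ₎ − y₍₁₎)/(n − 1) (the secant slope, i.e. both axes rescaled so
   the full curve has slope one), the cutoff index is the smallest
   i* = argminᵢ (y₍ᵢ₎ − s·i): the unique point where the slope-one line
   supports the curve from below, which is the discrete tangency point of
   the familiar hockey-stick plot. Ties — exact or within a 10⁻⁹ relative
   floating tolerance — break toward the smallest rank, which yields the
   larger SE set (on an exactly affine curve every point ties and the
   entire curve above the minimum is called SE). Regions with signal
   **strictly above** the cutoff signal are SEs. Degenerate inputs (fewer
   than 3 regions, or all-equal signals) are errors, not silent answers.
   The construction is scale-free: multiplying all signals by c > 0 leaves
   the SE/TE partition unchanged (property-tested).
4. **Condition specificity.** A target-condition SE is removed if it
   overlaps (≥ 1 bp — "unique to" means zero overlap) any background
   condition's SE, or lies on an excluded chromosome (default chrX).
   Removal counts are reported per class, background-overlap first.

## Variant QC

- MAF = min(p̂, 1−p̂) over non-missing calls, full sample by default
  (configurable); call rate = non-missing fraction.
- The Hardy–Weinberg test is the exact conditional test: given the allele
  counts, the heterozygote count has distribution
  P(h) ∝ 2ʰ N! / (n_AA! h! n_aa!); the p-value is the plain tail sum of
  configuration probabilities ≤ the observed one (no mid-p). The
  probability recurrence is accumulated in log space, so samples in the
  thousands cannot overflow. It is computed in controls only by default —
  disease association itself distorts HWE in cases — with the subset
  explicit and configurable.
- Filters: MAF ≥ 0.05 and HWE p ≥ 10⁻⁶ inclusive, call rate > 0.95 strict,
  taken verbatim from the usual inclusion-criteria phrasing; the
  strict-vs-inclusive distinction at the call-rate boundary is almost
  certainly immaterial in practice but is honored exactly. A removed
  variant is attributed to the first failing filter in the order
  (maf, hwe, call_rate); all-missing variants are flagged and counted
  separately, so kept + per-filter removals always partitions the input.
- SE intersection is half-open: a variant at SE.start is inside, at SE.end
  outside. Variants in no cancer-specific SE leave the analysis there.

## LD and tag selection

r² between two variants is computed from maximum-likelihood haplotype
frequencies under the random-union model, estimated by EM over the
double-heterozygote phase ambiguity (the PLINK-style estimator): all cells
of the 3×3 genotype table except the double-het contribute phase-known
haplotypes; the double-het count splits between cis/trans in proportion to
f_rr·f_AA vs f_rA·f_Ar. The EM starts at linkage equilibrium and stops when
no frequency moves by more than 10⁻¹⁰ (max 1,000 iterations); the
log-likelihood is non-decreasing across iterations (asserted in tests).
Pairs with a missing call at either locus are dropped; monomorphic input
yields an explicit "undefined" flag, never r² = 0. D' is reported alongside.

Clumping is greedy: seed with the smallest p-value (ties and the
no-p-value case fall back to the leftmost position), absorb every
unassigned variant with r² ≥ 0.8 to the seed, repeat. Membership is
seed-relative, not transitive — a chain A–B (0.9), B–C (0.9), A–C (0.5)
yields {A, B} then {C} — and the clumps always partition the variant set.
The pipeline clumps **before** association by default (tag selection is an
input-filtering step in the flowchart order) and tests tags only; the
opposite ordering (test everything, then clump on p-values) is available
via `clump_before_assoc=False`.

## Association

Case/control status is regressed on a genotype coding: additive (dosage
0/1/2), dominant (carrier), recessive (hom-alt), or codominant (het and
hom-alt indicators vs hom-ref; a contrast with an empty genotype class is
reported undefined while the other is still fit). Fitting is Newton/IRLS
with convergence at |Δ log-likelihood| < 10⁻¹⁰ (max 50 iterations), SEs
from the inverse observed information, and a separation flag when any
|β| > 15. On a lone binary predictor the fit reproduces the closed-form
2×2 cross-product OR and SE √(1/a+1/b+1/c+1/d) to 10⁻⁸ (property-tested;
also cross-checked against `statsmodels.Logit` on multi-covariate designs).
Wald 95% CIs (β ± 1.96·se, exponentiated) and two-sided Wald p-values match
the OR (95% CI) presentation convention.

Adjustment covariates are age, BMI, smoking as two dummies (ever, current;
never is reference), and binary family history; analysis is complete-case
per variant. The effect allele is the alt allele throughout.

Multiple testing uses Benjamini–Hochberg step-up: p₍ᵢ₎·m/i with a
cumulative minimum from the largest rank, capped at 1, stable under input
order. m defaults to the number of tests actually performed and is
configurable, since published FDR numbers are sometimes computed against
the full pre-filter scan size.

Stratified analyses fit the model per stratum (population strata split the
whole table; clinicopathologic subgroups compare each **case** subgroup
against the full control set) and summarise heterogeneity with Cochran's
Q = Σ wᵢ(βᵢ−β̄_w)², wᵢ = 1/seᵢ², df = strata−1, I² = max(0, (Q−df)/Q)·100,
and the χ²_df tail for p. Strata with undefined fits are excluded from Q
with a warning; a single usable stratum is an error.

## eQTL / expression concordance

The cis scan regresses log2 expression on risk-allele dosage (OLS,
two-sided t p-value) for genes whose TSS lies within ±1 Mb of the focal
variant, over samples with both genotype and expression; zero-variance
genes are skipped with a warning. Differential expression between tumor
and normal samples uses the two-sided Mann–Whitney U — exact when the
smaller group has ≤ 8 samples and the pooled values are tie-free, the
tie-corrected normal approximation otherwise — or Student's t-test;
log2 fold change is the mean difference on the log2 scale. A gene is
**concordant** iff eQTL p < α₁, DE p < α₂ (both default 0.05 — thresholds
are a package choice, flagged as such) and sign(eQTL β) = sign(log2FC),
with β oriented to the risk (odds-increasing) allele, so concordance always
implies both component significances.

## Synthetic-data generator

The generator emulates the statistical structure of the real inputs —
multi-condition H3K27ac-like peak tracks, a case-control genotype panel
with block LD, covariates, and a genotype-linked tumor/normal expression
matrix — at desk scale. Everything derives deterministically from one seed;
each component draws from its own fixed substream, so regenerating one
output never perturbs the others, and identical configs give byte-identical
files.

**Peak tracks.** Each condition gets gamma-distributed background peaks
(default Gamma(8, 0.25), mean 2) placed uniformly outside TSS windows, plus
planted clusters of 10 peaks spread over 40 kb (pairwise gaps well inside
the stitch distance) whose signals are multiplied by 20 — an SE:TE region
signal ratio of ~100×, in line with real rank curves where SEs carry an
order of magnitude more signal per constituent across many constituents.
"Shared" clusters appear in every condition; "specific" clusters (and one
chrX cluster, to exercise the chromosome filter) only in the cancer
condition, so the expected cancer-specific SE set is known exactly. These
defaults were fixed once against the planted-recoverability requirement
(all planted clusters, no background region, in ≥ 95/100 seeds — measured
98/100) and are not tuned per test.

**Genotypes.** Variants come in LD blocks (default 10 blocks of 5). Within
a block, each haplotype allele copies the previous variant's allele with
probability c = √r²_target and otherwise redraws from the block allele
frequency — a first-order chain that preserves every variant's frequency
exactly, gives adjacent-pair haplotype r² equal to the target with
geometric decay at distance, and reduces to identical vectors at r² = 1 and
independence at r² = 0. The default within-block r² is 0.95, reflecting the
high-LD tag pairs this design targets (reported pairs are r² ≈ 0.98) and
comfortably above the 0.8 clump threshold so a block clumps to one tag.
The causal variant is the leftmost member of the first block, which sits in
the central three-quarters of the first autosomal specific cluster (inside
the stitched SE footprint regardless of peak jitter); leftmost placement
makes it the positional clump seed when p-values are absent. Missingness is
Bernoulli per call (default 2%).

**Phenotypes.** Because the odds ratio is the estimand of a retrospective
design, genotypes are generated for a population pool of
pool_factor × (n_cases + n_controls) samples (default 4×), and
`gen_phenotypes` rejection-samples: each pool member gets covariates and a
Bernoulli status from logit P(case) = β₀ + log(OR)·dosage + covariate
terms (continuous covariates centered), and members are accepted in pool
order until both quotas fill (error if the pool is exhausted — raise
`pool_factor` or `baseline_prevalence_logit`). Covariate distributions are
a package choice, fixed and documented: age ~ N(65, 7), BMI ~ N(27.5, 4.5),
smoking (never/ever/current) ~ (0.45, 0.43, 0.12), family history ~
Bernoulli(0.08); default covariate log-ORs are modest (0.02/yr, 0.01 per
kg/m², 0.15/0.30 for ever/current smoking, 0.70 for family history). Cases
additionally receive clinicopathologic labels (Gleason, PSA group, stage)
for case-only subgroup analyses. Default planted effect: additive OR 1.5
at MAF 0.2, within the common-variant range this design targets.

**Expression.** The first 200 pool samples form the expression cohort with
random tumor/normal labels. Four genes within ±1 Mb of the causal variant
mirror the typical several-candidate situation at a risk locus: the target
(dose effect β = 0.5 log2/allele **and** tumor shift +1), a dose-only
decoy, a shift-only decoy, and a null gene; Gaussian noise (σ = 0.5).
Only the target should pass the concordance filter.

**What the generator does not model:** read-level data, imputation
uncertainty (hard calls only), population stratification or relatedness,
inter-individual enhancer variability, expression count noise
(log2-Gaussian only), LD between blocks. Passing tests therefore
demonstrate correctness of the algorithms and calibration of the
statistics under these idealised conditions — not robustness to the
confounders of real cohorts.

## Problem sizes and determinism of the test suite

Default study conditions — 1,500 cases / 1,000 controls from a 10,000
pool, 50 variants, ~150 peaks per condition on 4 autosomes + chrX — are a
deliberate desk-scale emulation of a much larger design; calibration tests
that need the published sample size (OR recovery at 4,000/3,000) set it
explicitly. Monte-Carlo checks (CI coverage ≥ 90/100 seeds, type-I error
in [0.035, 0.065] at 1,000 null variants, end-to-end planted recovery
≥ 90/100 — measured 96/100) iterate over fixed seed lists, so the suite is
deterministic. Hypothesis-based property tests run derandomized.

## Known limitations

- The discrete tangency point is sensitive to single outlier regions just
  below the planted signal range; on real data the SE/TE boundary is
  genuinely fuzzy and the cutoff should be treated as a ranking device,
  not a biological constant.
- The two-locus EM can in principle stop at a boundary local optimum for
  extreme tables; with the linkage-equilibrium start this was never
  observed in the property tests, and the `converged` flag is exposed.
- Wald CIs and the |β| > 15 separation heuristic misbehave for very sparse
  genotype classes (e.g. recessive contrasts with a handful of hom-alt
  carriers); the fit reports, rather than hides, non-convergence.
- BH assumes independence/PRDS across tests; tags within a window are
  nearly independent after clumping, but no attempt is made at
  permutation-based FDR.
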