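# Methods

## The problem

Genotyping every subject on a genome-wide array is expensive for a rare
disease. DNA pooling (SNP-MaP) hybridizes *pooled* case DNA and pooled
control DNA on a handful of replicate arrays and reads, per SNP, a relative
allele frequency (RAF) from the two fluorescence channels:

    f = G_raw / (G_raw + R_raw)

The pipeline tests, per SNP, whether the mean RAF differs between the case
pool and the control pool, then annotates and prioritizes the hits, tests
pathway over-representation of the implied gene set, and provides the
statistics used when candidate SNPs are re-genotyped individually in a
second cohort.

## The pooled test

For pool k ∈ {1 = case, 2 = control} with n_k replicate arrays and N_k
individuals, write f̄_k for the mean replicate RAF. Two variance components
enter:

* **binomial sampling variance** of the pool's allele frequency over its
  2N_k chromosomes, v_k = f̄_k (1 − f̄_k) / (2 N_k) — the pool is one draw
  of 2N_k alleles from the population;
* **replicate measurement error**, ε_k² = Σᵢ (f_ik − f̄_k)² / (n_k (n_k − 1)),
  the squared standard error of the replicate mean.

The statistics:

    T₁     = (f̄₁ − f̄₂)² / (v₁ + v₂)
    T_comb = (f̄₁ − f̄₂)² / (v₁ + v₂ + ε₁² + ε₂²)
    Z      = (f̄₁ − f̄₂) / sqrt(ε₁² + ε₂²)

T_comb ≤ T₁ always. T_comb is a squared standardized difference of two
proportions, so its p-value is taken from the upper tail of χ²(1 df)
(equivalently a two-sided Normal test on √T_comb). A SNP is a genome-wide
hit when p < 1×10⁻⁷ (strict inequality; configurable).

Degenerate cases: all four variance terms zero with equal means gives
p = 1; with unequal means the statistic is infinite and the SNP is reported
at the smallest representable p and flagged rather than dropped.

### QC before testing

1. failed hybridizations (both channels zero) are deleted;
2. a SNP is dropped when **either** pool retains fewer than 3 replicates —
   the per-pool reading is the conservative interpretation of a minimum
   replication rule;
3. X, Y and mitochondrial loci are dropped: pooling mixes male and female
   DNA, making intensities on those chromosomes uninterpretable.

## Hit prioritization

* **Odds ratio from RAF**: OR = f̄₁(1−f̄₂) / [f̄₂(1−f̄₁)] with
  SE(ln OR) from the allele-count approximation
  √(1/(2N₁f̄₁(1−f̄₁)) + 1/(2N₂f̄₂(1−f̄₂))) and a Wald 95% CI.
* **FPRP** (false-positive report probability): with prior π that the
  association is real and power 1−β = Φ(ln(OR_alt)/SE − z₁₋ₚ/₂) at an
  alternative OR_alt, FPRP = p(1−π) / [p(1−π) + (1−β)π]. Defaults: π over
  the grid {0.25, 0.1, 0.01, 0.001} and OR_alt = 1.5; both are exposed
  because no single prior is canonical.
* **SNP→gene mapping**: a gene whose span widened by 20 kb on each side
  (closed interval — exactly 20,000 bp away still counts) covers the SNP is
  assigned; *all* overlapping-window genes are kept, rendered "A/B" in
  reports. In a gene desert the nearest gene on each side is assigned
  (ties within a side broken by smaller start, then symbol). Per gene, the
  minimum p over its SNPs is kept (position breaks ties); the enrichment
  study set is the genes with p < 1×10⁻⁵ (strict).

## Pathway over-representation

With a study set of n genes from a reference universe of N, a pathway
holding K universe genes is expected to contribute K·n/N study genes.
Significance is the exact hypergeometric upper tail P(X ≥ k_obs); the
E-ratio is observed/expected. Benjamini–Hochberg step-up adjustment is
applied across pathways with at least one study-set gene; the total test
count m can be overridden (needed when reproducing adjusted values from a
run whose tested-category count is known — the published pathway table is
consistent only with m = 27). The reference size N defaults to the union of
the gene sets when read from GMT, or to the annotated gene count in
pipeline runs, and is always overridable since enrichment services rarely
publish their internal universe.

## Validation-cohort statistics

* **HWE**: 1-df χ² goodness of fit to ((1−q)², 2q(1−q), q²) at the sample
  allele frequency; monomorphic tables fit trivially (χ²=0, p=1). A
  conditional exact test (Levene distribution over heterozygote counts,
  probability ordering) is available for rare-allele tables where the χ²
  approximation is poor.
* **2×3 genotype association**: Pearson χ² without continuity correction;
  genotype columns empty in both groups are dropped first (df shrinks
  accordingly); a single remaining genotype class is an error, not a p-value.
* **Allelic OR**: allele-count 2×2 (minor = n₁+2n₂, major = 2n₀+n₁), Woolf
  CI. The Haldane–Anscombe +0.5 is applied to all four cells only when some
  cell is zero (`correction="zero-cell"`, the reporting default). The
  smoothed Gart estimator (`correction="always"`) is nearly unbiased for
  ln(OR) at rare-allele counts — exact enumeration at MAF 0.024 and 500
  alleles per group gives bias +0.032 for the raw estimator vs +0.0003 for
  Gart — so the simulator-recovery checks use it; a bias test run with the
  raw estimator would measure estimator bias, not simulator error.
* **Response classification**: complete response is post-treatment platelet
  count > 100×10⁹/L; partial response requires ≥ 30×10⁹/L **and** at least
  doubling of baseline (the inclusive-or reading, under which doubling from
  a very low baseline alone qualifies, contradicts the usual nonresponse
  definition; it remains available behind `rule="inclusive"`).
* **Platelet trajectories**: per-timepoint Welch t-tests between genotype
  groups at days 1, 3, 5, 7, 11, 14, flagged at 0.05 and 0.01; two
  zero-variance groups with equal means give p = 1.

## The synthetic-data generator

Defaults encode the emulated two-stage design: discovery pools of 200
cases / 200 controls with 3 replicate arrays each; a validation cohort of
250/250.

Pooled stage, per SNP: control truth f₀ ~ Uniform(0.05, 0.95); spiked SNPs
(the first `n_spiked`) add Δf = 0.15 to the case truth (clamped to [0,1]).
Each pool's realized frequency is Binomial(2N, f)/2N — exactly the v_k
component. Each replicate reads the realized frequency plus
Normal(0, noise_sd) truncated to [0,1] — the ε² component; noise_sd
defaults to 0.01. Channel intensities are G = s·RAF·(1+u),
R = s·(1−RAF)·(1+u) with a *shared* brightness factor u ~ Normal(0, 0.02)
per replicate, so G/(G+R) returns the replicate RAF exactly and the two
modeled variance components are the only error sources. SNPs are tiled over
the 22 autosomes at 1 kb spacing.

Cohort stage: the case allele frequency implied by a control MAF q and an
allelic OR is p = OR·q/(1−q+OR·q); genotypes are Binomial(2, p) within each
group (HWE by construction). Treatment response is Bernoulli with
carrier/non-carrier probabilities (defaults 0.85 / 0.60); platelet series
follow a logistic rise from a baseline below 30×10⁹/L toward a plateau that
depends on carrier status and on responding, plus Normal noise.

All randomness derives from one integer seed through documented
`SeedSequence` spawn keys (pooled = 0, cohort = 1, response = 2), so the
three generators are independently reproducible.

**What the generator does not emulate**: linkage disequilibrium between
SNPs, population stratification, batch effects, allele-specific
hybridization bias (which makes real pooled RAF a *relative*, not absolute,
frequency), and sex chromosomes. Passing calibration and recovery tests
therefore demonstrates correctness of the statistical machinery under the
modeled noise, not robustness to artifacts of real arrays.

## Measured behavior at the default settings

* Null calibration: on 10,000 null SNPs the combined test rejects at
  0.045 for α = 0.05 and 0.008 for α = 0.01 — within ±0.01 of nominal. The
  slight conservatism reflects estimating v_k from the observed means and
  ε² from only 3 replicates.
* Cross-pool correlation of mean RAF on null data is r² ≈ 0.986. The
  binomial pool variance at N = 200 caps r² near 0.986 regardless of
  noise_sd, so higher published correlations imply either larger pools or
  variance sources not captured here.
* Spike-in recovery: on a 100-SNP candidate panel with 10 spiked SNPs
  (Δf = 0.15), a spiked SNP ranks in the top 10 by T_comb in ≈ 96% of
  draws. Requiring *all ten* simultaneously in the top 10 succeeds in only
  ~63% of panels (and ~23% at a 1000-SNP panel): with pools of 200, the
  per-SNP signal-to-noise is √T_comb ≈ Normal(4.1, 1) against a null
  maximum around 3.5, so occasional rank swaps are intrinsic to the design,
  not an implementation artifact. The recovery rate is therefore reported
  per spiked SNP.

## Problem sizes in tests and the acceptance script

The suite and `scripts/acceptance.py` use 10,000 SNPs for null calibration,
100 panels of 100 SNPs for recovery, and 200 cohort replicates for OR
recovery — sizes at which the Monte-Carlo error of each reported rate is
well below the tolerance being checked while the whole run stays in the
seconds range.

## Known limitations

* The intensity TSV dialect is project-defined; vendor raw formats are not
  parsed.
* The pooled OR and its CI use pooled mean RAFs as if they were allele
  counts; replicate error is not propagated into that CI (it is into FPRP
  via the SE grid the caller supplies).
* BH adjustment with an m_total override reproduces published adjusted
  values only if the true tested-category count is supplied.
* The exact HWE test enumerates heterozygote configurations; it is
  intended for single-SNP validation tables, not genome-wide scans.
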