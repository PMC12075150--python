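# Methods

This note documents the models implemented in `boagwas`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions that matter for reproducibility.

## Thermotolerance phenotypes

**THI.**  The temperature–humidity index is

    THI = (1.8·T + 32) − (0.55 − 0.0055·RH)·(1.8·T − 26)

with T the dry-bulb air temperature in °C and RH the relative humidity in
percent.  The first term is the Fahrenheit dry-bulb temperature; the second
is a humidity correction that vanishes at RH = 100 and at T = 130/9 °C
(≈14.44 °C, where 1.8T − 26 = 0).  This is the standard validated livestock
heat-stress index.  The source literature for this trait prints the formula
with corrupted parenthesisation; the reconstruction above is the only
reading consistent with that standard form, and the closed-form anchor
points (THI = 86.0 at T = 30 °C/RH = 100 %; THI = 58.0 at T = 130/9 °C, any
RH) are asserted in the tests.

**THI load.**  Daily load is Σₕ max(THIₕ − 70, 0) over hourly THI values —
the cumulative excess above the 70 baseline.  Hours at or below the
baseline contribute zero; a "cumulative deviation above a baseline" without
the clamp could go negative on cool days and is not a load.  The clamp
matters only for days with sub-baseline hours (typical focal days are hot
throughout); it is a deliberate reading, exposed via the `baseline`
argument.

**TSS.**  For each animal, on its group's focal day,

    TSS = (VTmax − VTmin) / THI_load × 100.

VT extrema are taken over the *raw* 15-minute logger records of that day;
hourly averaging is applied only to the environmental series when matching
VT to THI.  The focal day is the rain-free calendar day with the highest
THI load among the logger's interior days (first and last day are dropped —
device insertion/removal artifacts); ties break to the earliest date.  A
zero THI load leaves TSS undefined and the record is reported missing —
never zero (which would claim perfect thermoregulation) nor infinite.
TSS is invariant to adding a constant to all VT records and scales linearly
in the diurnal range; both are property-tested.

**Hair lengths.**  Image measurements are converted at 2.145 mm per 1000
pixels.  Outliers are removed in a single pass per hair class (short/long)
using the cohort-wide mean and population SD (ddof = 0): values more than
3 SD from the mean are dropped, then each animal's phenotype is the mean of
its retained lengths.  The SD scope (cohort vs animal) is genuinely
ambiguous in the field; cohort-wide is implemented because per-animal SDs
from ≤5 hairs are too unstable to define a fence.

**Descriptives.**  The trait summary (N, mean, SD, min, max, CV %) uses the
sample SD; `coefficient_of_variation(mean, sd) = sd/mean·100` reproduces
published trait CVs from published means and SDs (e.g. 130.53/299.56 → 43.57 %
for sweat gland area).

## Genotype QC, AFD filter, BOA encoding

QC order is fixed: animals with genotype completion below 90 % are removed
first; marker MAF (< 5 % removed) and call rate (< 99 % removed) are then
computed on the retained animals.  Inequalities are strict "below", so MAF
exactly 0.05 survives.  The order matters — it changes survivor sets — and
animal-first is the standard PLINK workflow.  After QC, dosages are recoded
so the counted allele is the minor allele in the analyzed cohort (ties at
0.5 unchanged; the operation is idempotent).

Ancestry-informative markers are selected by the allele frequency
difference between purebred reference panels: |p̂_Angus − p̂_Brahman| ≥ 0.05,
with frequencies from simple allele counting ignoring missing calls (no
shrinkage).  Local-ancestry diplotypes are encoded AA→0, AB/BA→1, BB→2
Brahman-origin alleles; hard calls only — posterior probabilities from the
upstream caller are not propagated.

## Kinship and the mixed model

The VanRaden matrix is G = Z꜀Z꜀′ / (2Σpᵢ(1−pᵢ)) with Z꜀ = dosage − 2p and p
estimated from the analyzed sample; missing dosages are mean-imputed (2p),
contributing zero after centring.  Rows of G sum to zero by construction.
LOCO matrices are formed by subtracting each chromosome's numerator and
denominator share from the genome-wide sums, so the excluded chromosome
has provably no influence.

The model y = Xb + (marker terms) + g + e, g ~ N(0, Gσ²g), e ~ N(0, Iσ²e),
is fitted via the spectral decomposition G = UDU′: rotating by U′ makes the
covariance diagonal, σ²·(h²λᵢ + 1 − h²) with h² = σ²g/(σ²g+σ²e).  The
likelihood is profiled: GLS estimates and the scale σ² are closed-form at
each h², and h² is maximized by bounded Brent search on [0, 1−10⁻⁶] with
tolerance 10⁻⁸.  Numerical details:

* non-positive eigenvalues are floored at 10⁻¹⁰ before fitting (the
  centred G always has a zero eigenvalue along the ones vector);
* a flat profile (e.g. G = I, where only σ²g+σ²e is identified) resolves to
  the h² = 0 boundary by an explicit tie rule, collapsing to OLS;
* with h² pinned at 0 and G = I the Wald tests equal textbook OLS Wald
  tests to 10⁻¹⁰ (tested), and the rotated likelihood/GLS/Wald pipeline
  matches a brute-force implementation with explicit V⁻¹ to better than
  10⁻⁶ on random instances (tested).

**Criterion.**  ML is the default and variance components are re-estimated
under each full per-marker model; REML and estimate-once-per-chromosome are
available flags.  ML matches the single-marker diagonalization tools common
in this literature.  For *heritability estimation* the experiments use
REML: ML carries the classical downward bias in σ̂² from estimated fixed
effects (≈p/n), which tilts ĥ² upward — measured at +0.015 for n = 500 with
6 fixed effects, while REML was unbiased (mean 0.402 over 60 cohorts at
true 0.4).

**Wald tests.**  Single effects use (β̂/se)² against χ²₁; the joint SNP+BOA
test uses β̂′Cov(β̂)⁻¹β̂ over the two marker coefficients against χ²₂.  The
covariance uses the ML scale (RSS_w/n).  A marker column numerically inside
the span of the preceding design (relative least-squares residual below
10⁻⁸) is dropped — the BOA column loses in the joint model — with the df
reduced and an `aliased` flag set; this reproduces the observed collapse of
identical SNP and BOA signals at perfectly breed-fixed loci.  A monomorphic
covariable (constant column, aliased with the intercept) yields a missing
result for single-effect models.  For the joint model the per-effect 1-df
p-values from the same fit are emitted alongside the 2-df joint p; the
results table's `p` column carries the model's headline test (joint for
SNP+BOA).

**Fixed effects.**  X is an intercept plus collection-group dummies; one
phenotype record per animal, so the random-effect incidence is the
identity.  Animals missing a trait are dropped for that trait.

## Thresholds and QTL intervals

With M tests for a trait×model (markers actually tested: post-QC, post-AFD,
non-aliased, finite p), the genome-wide cutoff is 0.1/M (Bonferroni at
α = 0.1) and the suggestive cutoff 1/M.  QTL intervals are greedy clusters:
suggestive markers pooled across models, merged along a chromosome while
successive passing positions are within `gap_bp` (default 1 Mb,
configurable); bounds are min/max member positions (1-based inclusive),
the lead marker is the smallest p, supporting models are all models with a
passing member, and the interval is "significant" iff any member beats its
model's Bonferroni cutoff.  Reported admixture-mapping intervals in the
literature are wide and heterogeneous and no merging rule is standard, so
this rule is the pipeline's own convention and its parameter is surfaced.
Because ancestry LD is long-range, BOA-driven QTLs legitimately produce
multi-megabase intervals (visible in `examples/04`).

## The synthetic cohort generator

The generator defines the study conditions for every simulation-based
check.  Defaults: n = 500 individuals, m = 2000 markers uniformly spaced on
29 chromosomes of 1 Morgan (1 cM ≈ 1 Mb), founder FST 0.2, Brahman
admixture proportion π_B = 0.375, g = 8 generations since admixture,
polygenic variance 0.4, residual variance 0.6 (true h² = 0.4), 4 collection
groups with effect SD 0.5, trait mean 0.

* **Founders**: Balding–Nichols — ancestral p ~ U(0.05, 0.95), daughter
  frequencies Beta(p(1−F)/F, (1−p)(1−F)/F) independently per breed,
  clipped to [0.01, 0.99].  A single FST for both daughters; taurine–
  indicine divergence is high and the AFD filter makes downstream behaviour
  insensitive to the exact value.
* **Ancestry**: each haplotype is a two-state Markov chain along the map
  with stationary distribution (1−π_B, π_B) and resampling probability
  1 − exp(−g·d) between markers d Morgans apart.  This is distributionally
  identical to Poisson(g per Morgan) crossover events with iid tract
  ancestries — verified against an explicit crossover-point simulator — and
  matches the window/tract structure local-ancestry callers assume.  A
  pedigree gene-drop is deliberately not implemented.
* **Phenotypes**: y = μ + group + Σq a_q·SNP_q + Σq c_q·BOA_q + g + e with
  the polygenic term realized through per-marker effects
  u ~ N(0, σ²g/(2Σp(1−p))) on centred dosages, so Var(g) = σ²g·G for
  exactly the VanRaden G the model fits.  The stored decomposition sums to
  y identically.
* **Loggers**: VT(t) = 38.6 + A·cos(2π(t−16)/24) + ε with ε ~ N(0, 0.05²)
  by default; weather is a sinusoid peaking at 16:00 with humidity in
  antiphase (defaults give a subtropical summer day with THI > 70 all day).
  On noise-free data the derived TSS equals 2A/load·100 analytically.

What the generator does **not** emulate: array LD within ancestral breeds
beyond Markov tract structure, allele-frequency estimation error in real
reference panels' descendants, genotyping error, pedigree relatedness
beyond admixture relatedness, selection or assortative mating, more than
two ancestral populations, and local-ancestry caller mistakes (true BOA is
supplied; a caller's errors would attenuate BOA effects).  Passing tests
therefore demonstrate correctness of the statistical machinery under the
assumed model, not robustness to miscalled ancestry.

## Validation experiments (`boagwas.experiments`)

* **Type-I error**: one default cohort under the global null (polygenic
  background only), all markers scanned under the three models against the
  *genome-wide* G.  Size at nominal 0.05 stays inside 0.05 ± 0.015.  The
  genome-wide matrix is used deliberately: under LOCO the tested marker
  tags real local polygenic variance that LOCO leaves unmodelled — that is
  the power LOCO exists to preserve, not a size error — and measured
  rejection rates under LOCO (0.07–0.12) reflect that true signal.
* **Heritability recovery**: REML mean over 20 replicate cohorts, within
  ±0.05 of the simulated 0.4.  Per-cohort ĥ² has SD ≈ 0.09 at n = 500, so
  the band is ≈2 standard errors of the mean.
* **Detectability contrast**: the planted QTL sits at the least
  ancestry-informative AFD-passing marker that is also a common variant
  (expected cohort MAF ≥ 0.2 — mirroring the MAF ≥ 5 % QC every tested
  marker passes; at rare-variant markers no allele-effect test has power
  and the contrast would be vacuous).  An ancestry-driven effect (0.4 per
  Brahman-origin allele) is detected at the Bonferroni cutoff by the BOA
  and joint models in ≥ 95 % of replicates while the SNP model detects
  ~0 %; an allele-driven effect (0.45 per minor allele) at the same marker
  reverses the outcome.  Effect sizes come from a power calculation at
  n = 500 (non-centrality ≈5–6 SE, comfortably separating the two regimes).
  Detection is judged at the planted marker itself with its LOCO kinship.

Problem sizes throughout (n = 500, m = 2000, 20 replicates; demo pipeline
n = 300, m = 2000, 5 chromosomes) are the package's chosen desk-scale study
conditions: large enough for the asymptotics the tests rely on, small
enough that the whole suite and the acceptance script run in minutes.

## Known limitations

* Real headline findings in this literature come from cohorts of thousands
  of animals; desk-scale synthetic cohorts validate the machinery, not the
  biology.
* The estimated-h² Wald test uses the ML scale without a small-sample df
  correction; at n = 500 the effect on size is < 0.01.
* Local-ancestry inference itself (the haplotype HMM) is out of scope; the
  pipeline consumes hard diplotype calls or simulates truth.
* VCF / PLINK 2 / phased-haplotype formats, sex chromosomes, multi-trait
  models, dominance/epistasis, and gene-set enrichment are out of scope.
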