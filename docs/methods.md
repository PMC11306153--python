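# Methods

## Model and scope

`pqtlmr` implements two-sample Mendelian randomization (MR) from GWAS
summary statistics, specialised to the proteome-wide setting: exposures are
circulating protein levels instrumented by cis-pQTLs, the outcome is a
binary disease trait on the log-odds scale, and the analysis is repeated
across many proteins (proteome screen) or many outcomes (PheWAS screen)
with false-discovery-rate control.

For variant *j*, let β̂ₓⱼ (SE σₓⱼ) be the per-allele effect on the
standardized protein level and β̂ᵧⱼ (SE σᵧⱼ) the log-odds effect on the
outcome, both aligned to the same effect allele. Under the linear
structural model β̂ᵧⱼ ≈ θ·β̂ₓⱼ + αⱼ, where θ is the causal log-odds effect
per SD of protein and αⱼ a direct (horizontally pleiotropic) effect, each
variant yields the Wald ratio θ̂ⱼ = β̂ᵧⱼ/β̂ₓⱼ with first-order SE
σᵧⱼ/|β̂ₓⱼ|.

## Instrument selection

Per protein, in order:

1. **Significance** — retain variants with p strictly below `p_threshold`
   (default 5×10⁻⁸; the boundary value itself is excluded).
2. **MHC exclusion** — drop variants on chromosome 6 in
   [28,477,897, 33,448,354] (inclusive), where extreme LD makes
   instruments untrustworthy.
3. **cis filter** — keep variants within `cis_window` (1 Mb) of the gene
   *body* (start/end, not TSS; inclusive bounds, same chromosome).
4. **LD clumping** — greedy: visit variants by ascending p (ties broken by
   variant id for determinism), keep the visited variant, remove remaining
   variants on the same chromosome within `clump_window` (10,000 kb) with
   r² > `clump_r2` (0.001) against it. LD is supplied explicitly (pair
   table, block file, or dense matrix); variants absent from the LD input
   are treated as uncorrelated and logged.
5. **Instrument strength** — keep variants with F = (β̂ₓ/σₓ)² strictly
   above `f_min` (10). The per-variant squared z-ratio is used as F; no
   sample-size-based formula is assumed.
6. **Outcome overlap** — after matching to the outcome table, drop
   instruments with outcome p < 5×10⁻⁸ (or absent from the outcome).
   The predicate depends only on the outcome record, so it is applied on
   the selected exposure table before harmonization; the resulting set is
   identical to applying it after.

Steps 1–3 are independent row predicates and commute; clumping is
order-sensitive and always runs after them. All filters are idempotent.

## Harmonization

Matching is by variant id. Outcome records are aligned to the exposure's
effect allele: identical labels are kept; swapped labels negate β̂ᵧ and
complement the outcome frequency; complementary-strand labels (A↔T, C↔G
applied to the outcome pair) are resolved to one of those two cases when
`allow_strand_flip` (default on). Palindromic variants (A/T, C/G pairs)
cannot be resolved from labels: they are kept only when both allele
frequencies are present, both lie outside the ambiguity zone
(0.5 ± `palindromic_eaf_tolerance`, default 0.08 — so eaf ∈ (0.42, 0.58)
drops), and both fall on the same side of 0.5 after label alignment;
otherwise they are dropped, as are records lacking a frequency. Every
decision is logged per variant (kept / sign_flipped / strand_flipped /
dropped_palindromic / dropped_incompatible / dropped_missing); the kept +
dropped categories partition the exposure variants. Whether an original
analysis inferred strand or dropped all palindromes is rarely knowable;
both policies are reachable through the configuration.

## Estimators

* **IVW** — θ̂ = Σwⱼθ̂ⱼ/Σwⱼ with first-order ratio weights
  wⱼ = β̂ₓⱼ²/σᵧⱼ² (σₓ is deliberately ignored in the weight, the standard
  two-sample convention; it is used by the bootstrap and MR-PRESSO).
  Algebraically identical to zero-intercept WLS of β̂ᵧ on β̂ₓ with weights
  1/σᵧ². Fixed-effect SE (Σwⱼ)^(−1/2); the multiplicative random-effects
  model (the primary estimate everywhere) multiplies it by
  max(1, √(Q/(L−1))). The floor keeps the MRE SE from undercutting the
  fixed-effect SE; it can be disabled (`mre_variance_floor=False`).
  With L = 1 the IVW reduces to the Wald ratio. P-values are two-sided
  normal.
* **Cochran's Q** — Q = Σwⱼ(θ̂ⱼ − θ̂_fe)², referred to χ²(L−1);
  undefined (reported missing) for L < 2. Both fixed- and random-effects
  IVW are always computed; the MRE estimate is reported as primary rather
  than switching models on the observed Q, which keeps the reported SE a
  deterministic function of the data.
* **MR-Egger** (L ≥ 3) — weighted regression β̂ᵧ = α + θβ̂ₓ with weights
  1/σᵧ², after re-orienting each pair so β̂ₓ ≥ 0 (the intercept is
  orientation-dependent; the stored instrument set is never mutated).
  SEs carry a multiplicative overdispersion factor floored at 1; p-values
  use t(L−2), the small-L convention. The intercept estimates the mean
  directional pleiotropic effect under InSIDE.
* **Weighted median** (L ≥ 3) — ratios sorted ascending with normalized
  weights w′ⱼ; cumulative midpoints sⱼ = Σ_{k≤j}w′ₖ − w′ⱼ/2; the estimate
  linearly interpolates the ratio at s = 0.5 (clamped to the extreme
  ratios outside [s₁, s_L]). SE is the SD of the estimate over
  `bootstrap_iterations` (1000) parametric resamples
  β̂ₓⱼ* ~ N(β̂ₓⱼ, σₓⱼ), β̂ᵧⱼ* ~ N(β̂ᵧⱼ, σᵧⱼ), with weights recomputed per
  resample.
* **Weighted mode** (L ≥ 3) — argmax of a weighted Gaussian KDE over the
  ratios on a 512-point grid spanning the ratios ± 3 bandwidths; bandwidth
  φ·0.9·min(sd, iqr/1.34)·L^(−1/5) (φ = `mode_bandwidth_multiplier`,
  default 1). A degenerate bandwidth (identical ratios or zero IQR/SD)
  falls back to the highest-weight ratio. SE by the same bootstrap.
* **MR-PRESSO** (L ≥ 4) — observed RSS = Σⱼ wⱼ(β̂ᵧⱼ − θ̂₍₋ⱼ₎β̂ₓⱼ)² with
  leave-one-out IVW predictions θ̂₍₋ⱼ₎ and residual weights wⱼ = 1/σᵧⱼ²
  (residuals live on the β̂ᵧ scale, so outcome inverse-variance is the
  coherent weight). The null distribution comes from `presso_simulations`
  (1000) parametric replicates β̂ₓⱼ* ~ N(β̂ₓⱼ, σₓⱼ),
  β̂ᵧⱼ* ~ N(θ̂₍₋ⱼ₎β̂ₓⱼ, σᵧⱼ), recomputing the leave-one-out fits per
  replicate. Global p = fraction of simulated RSS ≥ observed; per-variant
  outlier p = fraction of simulated j-th residuals ≥ observed,
  Bonferroni-multiplied by L and flagged below 0.05; when any variant is
  flagged, IVW on the remainder is reported as the outlier-corrected
  estimate. Empirical p-values are floored at 1/n_simulations (analytic
  p-values are floored at the smallest positive double). Note the test's
  operating regime: with few instruments, a single outlier of dominant
  weight contaminates every leave-one-out fit *and* its own simulated
  null, so detection is only reliable when each instrument is a small
  fraction of the total weight.

Effects are exponentiated to odds ratios with Wald 95% CIs
(exp(β̂ ± 1.96·SE)). All estimators are invariant under joint per-variant
sign flips (allele relabelling); bootstrap and simulation streams are
seeded and single-threaded, so a fixed seed reproduces results bit for
bit.

## Screening

`run_proteome` maps the per-protein analysis over the panel and applies
Benjamini–Hochberg step-up adjustment (via
`statsmodels.stats.multitest.multipletests`, checked in the tests against
a literal step-up implementation) to the primary IVW-MRE p-values. The
FDR family is the set of proteins with a successful primary fit in the
current run — not the full assay panel — and the family size is reported
alongside the counts; with m ambiguous in published screens, this is the
one self-consistent choice available to a reproducible tool. Per-analysis
bootstrap seeds are derived from the run seed and the protein id (CRC32),
so results are invariant under input reordering.

`run_phewas` fixes one protein's selected instruments, excludes outcomes
with fewer than `min_cases` (50) cases before any fitting, re-harmonizes
and fits each retained outcome independently (no cross-outcome
correlation modelling — a marginal screen), and adjusts across the
retained family.

## Synthetic studies

The generator emulates the deCODE-exposure / FinnGen-outcome structure at
desk scale with analytically controlled signal:

* Effects live on the standardized-genotype scale, giving the closed forms
  σₓ = (2·maf·(1−maf)·n_exposure)^(−1/2) and
  σᵧ = (2·maf·(1−maf)·n_eff)^(−1/2) with
  n_eff = n_cases·n_controls/(n_cases+n_controls). Binary outcomes are
  generated through this effective-sample-size approximation rather than
  individual-level logistic simulation: the pipeline consumes summary
  statistics only, and this preserves the signal-to-noise structure.
* Defaults mirror the motivating study's dimensions: 35,559 exposure
  samples; 1,543 cases / 391,037 controls; 5 instruments per protein.
* Each protein gets L causal LD blocks inside its cis window (lead + 2
  correlated shadows at r² = 0.9), 8 null cis variants, and decoy variants
  inside the MHC carrying genome-wide-significant effects (so only the MHC
  filter can remove them). Genes cycle chromosomes 1–22; chromosome-6
  genes are placed adjacent to the MHC so their cis windows overlap it.
* Lead-variant true |z| is a uniform multiple c ∈ (1.2, 10) of the
  genome-wide threshold z (≈5.45), i.e. F roughly 43–2,970, spanning the
  weak-instrument region well above the F > 10 screen while keeping true
  outcome associations of a causal protein (θ ≈ ln 1.4) below the
  outcome-overlap exclusion threshold — with much stronger instruments
  that rule, applied as published, removes a causal protein's best
  instruments by design.
* LD is simulated at the z-score level (block-correlated noise), enough to
  exercise clumping deterministically; there are no individual genotypes,
  no realistic MAF spectrum, and no annotation-aware architecture.
* Pleiotropy: αⱼ = 0, N(0, τ²) (balanced) or N(μ, τ²) (directional),
  applied to a configurable fraction of instruments; shadows inherit
  r·α of their lead. Directional-pleiotropy recovery experiments use
  all-positive exposure effects: with random signs, the β̂ₓ ≥ 0
  orientation required by Egger flips α signs too and the mean directional
  effect is no longer identified.
* Outcome allele labels are scrambled (swap 30%, strand-flip 10% by
  default) to exercise harmonization losslessly; palindromic variants are
  off by default (`palindrome_fraction = 0`) so the default study keeps
  all 5 instruments — palindrome handling is tested directly.
* Everything is reproducible from (config, seed); the exposure, outcome
  and PheWAS generators draw from independent seeded streams.

What passing tests on these studies do **not** show: behaviour under
realistic LD panels, allele-frequency mismatch between cohorts,
sample overlap, winner's-curse in instrument selection, or non-linear
exposure-outcome relations. The generator is a correctness and
calibration harness, not a cohort emulator.

## Verification harness

The statistical guarantees are checked at these problem sizes (chosen to
give stable Monte-Carlo error at interactive runtimes): estimator algebra
against generic WLS on 200 random sets; recovery and 95% CI coverage at
θ = ln 1.40 over 1,000 replicates; type-I error over 2,000 null
replicates against the 99% binomial band; weighted-median robustness with
40% invalid instruments over 500 replicates; Egger-intercept recovery over
1,000 replicates; and FDR calibration over 200 repeated 200-protein
screens (20 causal), asserting the mean realized false-discovery
proportion at q < 0.05 stays within three Monte-Carlo SEs of the nominal
5%. Screens inside Monte-Carlo loops restrict the estimator suite to the
primary IVW-MRE: the q-values under study depend only on the primary
p-values, and the bootstrap sub-methods are orthogonal to those
properties.

## Known limitations

* No proxy-SNP lookup for instruments missing in the outcome, no
  multi-allelic or indel handling, no genome-build liftover (positions are
  an opaque shared coordinate system).
* No MR-RAPS, multivariable MR, colocalization or Steiger filtering.
* The weighted-mode bandwidth constants follow the usual rule of thumb and
  are configurable but not data-adaptive.
* MR-PRESSO detection degrades when one instrument dominates the total
  weight (see above).
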