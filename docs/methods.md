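# Methods

This note records the statistical model behind each component, the defaults
and why they were chosen, and the numerical conventions that affect results.

## Model and assumptions

Two-sample MR treats each SNP j as an instrument with exposure association
γⱼ and outcome association Γⱼ = θ·γⱼ + αⱼ, where θ is the causal effect of
the exposure (ln CRP) on the outcome (ALS log-odds) and αⱼ is any direct
(pleiotropic) effect. A valid instrument has αⱼ = 0 and is independent of
confounders; the estimators differ in how much deviation from that they
tolerate:

- IVW assumes all αⱼ = 0; it is the primary method.
- MR-Egger allows αⱼ ≠ 0 provided instrument strength is independent of
  the direct effects (InSIDE); its intercept estimates the mean α.
- The weighted median tolerates up to half of the weight coming from
  invalid instruments.
- The mode estimators require only that the largest homogeneous cluster of
  Wald ratios is the valid one.
- MR-PRESSO detects individual αⱼ ≠ 0 as residual outliers.

Estimates are reported per unit increase in natural-log CRP, as log-odds
with OR = exp(β) and z-based 95% CIs (z = 1.959964 throughout).

## Harmonization

Outcome effects are aligned to the exposure's effect allele by exact match,
allele swap (sign flip, EAF → 1−EAF), or strand complement. Palindromic
(A/T, C/G) pairs cannot be resolved by alleles: outside the intermediate
band they are oriented by allele-frequency concordance (both EAFs on the
same side of 0.5); inside the band — default (0.42, 0.58), a conventional
±0.08 tolerance around 0.5, configurable — and whenever an EAF is missing,
they are excluded conservatively. Every exclusion carries a machine-readable
reason; retained + excluded always sums to the shared-SNP count.

## Instrument QC cascade

Order: LD clump → harmonize → confounder filter → Steiger filter → F filter.

- **Clumping**: greedy by p-value, window 10 000 kb, r² cutoff 0.001
  (standard MR settings). A pair inside the window that is absent from the
  supplied LD matrix is a hard error; independence is never assumed
  silently. Ties on p break by variant ID for determinism.
- **Proxy lookup is deliberately absent**: instruments missing from the
  outcome GWAS are dropped with a logged reason. Proxy search needs an
  external LD reference service, and dropping is the transparent fallback.
- **Confounder filter**: a local annotation table stands in for
  PhenoScanner; a SNP is excluded iff annotated to a configured confounder
  trait (default list: LDL/total cholesterol, type 2 diabetes, childhood
  BMI, neutrophil and white-blood-cell counts, systolic/diastolic blood
  pressure) with p strictly below 5×10⁻⁸.
- **Steiger filter**: r² with each trait from 2β²·MAF(1−MAF), each
  dataset's own EAF folded to MAF; direction is TRUE iff r²_exp > r²_out
  (ties excluded — they are measure-zero in float data and the conservative
  call is exclusion). On the binary side the same formula is applied to
  log-odds betas; this is an approximation, and the filter is a single
  function so a liability-scale conversion can be swapped in. A Fisher-z
  two-sample test on the transformed correlations is reported alongside,
  using study-level sample sizes (204 402 / 80 610) when per-SNP n is
  absent.
- **F filter**: per-SNP F = β²/se², threshold 10.

## Estimators — numerical conventions

- **Wald ratio**: first-order delta-method SE (σ_y/|γ̂|), which reproduces
  published single-SNP CIs in this setting; a second-order option
  (adding Γ̂²σ_x²/γ̂⁴) is available behind a flag.
- **IVW**: closed-form weighted normal equations (weights 1/σ_y²);
  multiplicative random effects scale the fixed SE by √(Q/(L−1)) floored at
  1, with Q the Cochran statistic at the IVW fit — the same Q the
  diagnostics module reports (single source of truth). Normal inference.
- **MR-Egger**: instruments oriented to γ̂ > 0 before fitting (the
  regression is not sign-equivariant per SNP); residual variance scaled by
  max(1, Q′/(L−2)); slope and intercept tested on t(L−2). The t reference
  matters at small L: with four instruments an intercept |t| ≈ 2.2 has
  p ≈ 0.16 on t(2) but ≈ 0.03 on the normal.
- **Weighted median**: ratios ordered, inverse-variance weights (first-order
  ratio variance, matching the Wald-ratio SE definition) accumulated to
  midpoint fractions, linear interpolation at 0.5. SE = SD of the estimate
  over parametric bootstrap resamples of both betas (weights held fixed);
  default 1000 replicates, explicit seed required.
- **Mode estimators**: normal-kernel density over the ratios, bandwidth
  φ × 0.9·min(SD, 1.4826·MAD)·L^(−1/5) with φ = 1 by default; estimate is
  the argmax on a 512-point grid spanning the ratio range ±3 bandwidths;
  degenerate (all-equal) ratio sets return that common value. Weighted
  variant uses inverse-variance weights in the density. Bootstrap SE as for
  the median; p on t(L−1).
- **MR-PRESSO**: the leave-one-out bookkeeping variant (named in the result
  metadata): each SNP's squared weighted residual is taken against the IVW
  fit of the other SNPs, RSS_obs is their sum, and the null redraws both
  betas around the leave-one-out predictions. Empirical p-values use
  (k+1)/(n_sim+1); per-SNP outlier p are Bonferroni-adjusted across
  instruments (configurable to none); n_sim defaults to 1000. The
  distortion test resamples outlier-count replacement sets from the inliers
  with replacement and compares the absolute distortion coefficient.
  Identical seed + inputs give bit-identical results (numpy PCG64).

## Power

The binary-outcome noncentrality approximation:
power = Φ(√(N·R²·K(1−K))·|ln OR| − z_{1−α/2}), named in output metadata.
The minimum detectable OR inverts it by Brent root-finding on ln OR to
relative tolerance 1e−8. At OR = 1 the value degenerates to α/2 (one tail);
R² = 0 warns rather than raising. Calculators of this family differ in
small internal variants; the computed minimum detectable OR for the ALS
study conditions (N = 80 610, K = 0.258, R² = 0.0155) is 1.199.

## Synthetic-data generator

Emulates exactly what the pipeline consumes — summary statistics, not
genotypes. Per SNP: MAF ~ U(0.05, 0.5); true exposure effect |γ| ~
scale·U(0.5, 1.5) with random sign (default scale 0.05 SD/allele, giving
single-SNP F around 100–500 and ~50-SNP sets explaining ~2–3% of exposure
variance, the regime of a large CRP instrument set); standard errors from
the standard approximations se_exp ≈ 1/√(2·MAF(1−MAF)·n_exp) and
se_out ≈ 1/√(2·MAF(1−MAF)·n_out·K(1−K)); observed betas drawn normally
around their true values; outcome effects θγⱼ + αⱼ generated directly on
the log-odds scale. Default sample sizes are the study's (204 402 exposure;
80 610 outcome, 25.8% cases).

Pleiotropy modes: `none`; `balanced` (αⱼ ~ N(0, sd)); `directional`
(αⱼ = sign(γⱼ)·N(mean, sd) — sign-coupled so the Wald-ratio contamination
is one-sided on the exposure-increasing orientation, since allele labels
are arbitrary and only α/γ is estimable). `pleiotropy_fraction` restricts
the invalid set; `inside_violation` adds an instrument-strength-dependent
term. Structural features are planted deterministically and disclosed in
the truth record: intermediate-frequency palindromes (A/T or C/G, EAF
drawn inside the exclusion band), confounder-annotated SNPs (annotation
p = 1e−12 to a default confounder trait), and LD blocks (adjacent
positions, constant pairwise r); all other SNPs are placed ≥ 50 Mb apart so
clumping treats them as independent.

What the generator does **not** emulate: realistic genome-wide LD
structure, allele-frequency differences between studies, sample overlap,
winner's-curse selection of instruments, population stratification, or
liability-scale effects. Passing tests therefore demonstrate correctness of
the statistical machinery under the stated generative model, not robustness
to those real-data complications.

## Problem sizes in the checks

The repeated-simulation checks use sizes chosen to make Monte-Carlo error
small relative to the asserted margins: estimator coverage over 500
replicates of 30-SNP sets (bootstrap 300), MR-PRESSO type-I error over 500
replicates of 20-SNP sets at n_sim = 1000, parameter recovery over 200
replicates of 50-SNP sets, median-vs-IVW bias over 200 replicates with 40%
invalid instruments.

## Known limitations

- Correlated instruments are handled only by exclusion (clumping); there is
  no generalized-IVW with an LD-aware covariance.
- Steiger's outcome-side r² ignores the binary liability scale.
- The weighted-median weights use the first-order ratio variance; packages
  that use the second-order variance will differ slightly in the weights
  (not in the estimator's logic).
- Single-trait, single-direction analyses only: no multivariable MR, and
  the reverse-direction flag simply swaps the datasets and stops with a
  caveat when fewer than two instruments survive.
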