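# Methods

`cytomr` implements a two-sample Mendelian randomization (MR) battery for
screening quantitative exposures (circulating cytokines, in SD units)
against binary outcomes (site-specific cancers, log-odds scale) using only
GWAS summary statistics from two non-overlapping samples.

## Model and estimand

For instrument j, let γ̂_j (SE σ_Xj) be its association with the exposure
and Γ̂_j (SE σ_Yj) its association with the outcome, both expressed for a
common effect allele. Under the instrumental-variable assumptions the
per-SNP Wald ratio θ_j = Γ_j/γ_j estimates the causal log-odds β per 1 SD
of exposure. Horizontal pleiotropy enters as Γ_j = β·γ_j + α_j; the
diagnostics below target α_j ≠ 0.

## Instrument construction

1. **Selection** keeps SNPs with exposure p < 5×10⁻⁸ (strict inequality;
   configurable `p_instrument`).
2. **LD pruning** is greedy clumping: candidates sorted by ascending
   p-value (ties broken lexicographically by rsid for determinism); each
   kept SNP discards all later candidates with pairwise r² ≥ 0.1
   (`r2_prune`). Pairs absent from the LD table are treated as unlinked
   (r² = 0, logged at debug level). The output is order-independent and the
   globally most significant SNP always survives.
3. **Cross-exposure exclusion** removes any rsid instrumenting two or more
   exposures from all of their lists, as in a multi-cytokine screen.
4. **Harmonization** aligns the outcome record onto the exposure's effect
   allele: identical alleles copy the effect; swapped alleles negate it
   (and flip eaf); strand-complemented alleles are complemented first.
   Palindromic SNPs (A/T, C/G) are strand-ambiguous: policy `drop` removes
   them; the default `freq` aligns by the shared minor allele — the
   labelled effect alleles refer to the same physical allele iff both
   frequencies fall on the same side of 0.5 — and drops the SNP when
   either frequency is within the ambiguity bound of 0.5
   (`min(eaf, 1−eaf) ≥ 0.42`). Irreconcilable allele sets yield an
   explicit drop verdict with a reason code, never a silent omission.
5. **Instrument strength.** Per-SNP explained variance defaults to
   R²_j = 2f_j(1−f_j)γ_j² for a unit-variance exposure, falling back to
   γ_j²/(γ_j² + σ_Xj²N) when the allele frequency is missing. The set-level
   F-statistic defaults to F = R²(N−1−k)/(1−R²) (`f_formula="unadjusted"`);
   note this form omits the division by k of the classical multi-instrument
   F = [R²/k]·[(N−1−k)/(1−R²)], which is available as
   `f_formula="classical"` — the two differ by the factor k, and a debug
   note is logged when k > 1. Single-SNP F_j values are also provided.
   The pipeline records F and warns below `min_f = 10` (the conventional
   weak-instrument screen) but does not drop pairs on it, since the screen
   is reported, not enforced, in the analysis this battery reproduces.

## Estimators

* **Wald ratio.** SE defaults to the first-order delta term σ_Y/|γ|
  (`wald_se_order="first"`), which is what the IVW weighting implies for
  the summary estimates; the second-order form adds the exposure-noise
  term and is selectable.
* **IVW.** β̂ = Σw_jθ_j / Σw_j with w_j = se(θ_j)⁻²; fixed-effect
  SE = (Σw)^−1/2. Cochran's Q = Σw_j(θ_j−β̂)² on k−1 df drives the model
  choice: the default `auto` rule uses fixed effects when the Q-test
  p ≥ 0.05 (`het_alpha`) and otherwise a multiplicative random-effects
  model that scales the SE by max(1, √(Q/(k−1))) and leaves the point
  estimate unchanged. An additive (DerSimonian–Laird) variant is
  deliberately not implemented.
* **Weighted median.** θ sorted ascending; standardized cumulative weights
  p_j = (S_j − w_j/2)/S_k; the estimate interpolates θ against p at
  p = 0.5. The SE is a parametric bootstrap (default 1000 replicates,
  seeded): θ*_j ~ N(θ_j, se_j²), SE = SD of the replicate medians
  (ddof = 1). A simple-median variant (equal weights) is exposed as an
  option. Results are bit-reproducible for a fixed seed.
* **Maximum likelihood.** Maximizes Σ_j [log N(γ̂_j; γ_j, σ_Xj²) +
  log N(Γ̂_j; βγ_j, σ_Yj²)] over (β, γ_1..γ_k). The γ_j have a closed-form
  optimum for fixed β, so β is found on the profile objective
  (Nelder–Mead from the IVW start, objective tolerance 1e-10); the SE of β
  is the (β,β) element of the inverse observed information, computed by
  block inversion. As σ_X → 0 the estimate converges to fixed-effect IVW.
* **MR-Egger.** Instruments are first oriented so every γ_j > 0 (negating
  both effects where needed — required for the estimator's validity).
  Weighted least squares of Γ_j on γ_j with a free intercept and weights
  1/σ_Yj²; the intercept estimates the average directional pleiotropic
  effect (valid under InSIDE), the slope is the pleiotropy-adjusted causal
  estimate. Inference is t-based on k−2 df. Requires k ≥ 3.
* **95% intervals** everywhere use the multiplier 1.95996 and are reported
  on the odds-ratio scale; p-values are two-sided normal except where
  noted.

## MR-PRESSO

The global test regresses outcome on exposure effects through the origin
with weights 1/σ_Yj², takes each SNP's residual r_j = Γ̂_j − β̂₍₋ⱼ₎γ̂_j
against the leave-one-out slope, and refers RSS = Σw_j r_j² to a
Monte-Carlo null: γ*_j ~ N(γ̂_j, σ_Xj²), Γ*_j ~ N(β̂₍₋ⱼ₎γ̂_j, σ_Yj²),
re-computing the RSS identically per replicate. Empirical p-values carry
an add-one correction, so the floor is 1/(n_sim+1): the default
n_sim = 1000 resolves p down to ~10⁻³, and ≥ 10,000 replicates are needed
to resolve p-values of order 10⁻⁴. The outlier test flags SNP j when its
per-SNP empirical p falls below 0.05/k (Bonferroni; a raw threshold is
available). When outliers are flagged, the corrected estimate is the
fixed-effect IVW on the retained SNPs and the distortion statistic
(β̂_raw − β̂_corr)/β̂_corr is referred to a bootstrap null over random
same-size subsets (two-sided on |D|). With no outliers the distortion
stage is not invoked and the raw IVW estimate stands. The test needs
k ≥ 4 to be meaningful; below that it is marked not applicable. A strong
outlier can inflate other SNPs' leave-one-out residuals (swamping), so
"exactly the injected SNP flagged" holds for clean constructions, not as a
theorem.

## Sensitivity analyses

Leave-one-out re-runs IVW (auto model rule) with each instrument removed
in turn; the pipeline reports the maximum absolute deviation from the full
estimate. Exclusion-list reruns model a manual secondary-phenotype scan as
a user-supplied rsid→reason table (no network dependency): the surviving
set is re-estimated and the dropped rsids reported; unknown rsids warn
rather than fail.

## Grid orchestration

Each exposure–outcome pair runs selection → pruning → harmonization → F
screening → ratios → Q → IVW → weighted median → maximum likelihood →
Egger → PRESSO → leave-one-out; stages with unmet preconditions are
recorded as not-applicable. The primary IVW p-value is classified with
strict boundaries: p < α_bonf = 0.05/(n_exposures × n_outcomes) is
significant; α_bonf ≤ p < 0.05 is suggestive; otherwise null (for a 1×1
grid the two thresholds coincide and the suggestive band is empty).
α_bonf is always recomputed from the actual grid dimensions. Stochastic
stages draw per-pair seeds as master_seed XOR SHA-256(exposure|outcome),
kept below 2³¹, so grid results are independent of traversal order and
byte-reproducible. Per-pair failures surface as not-testable results
without aborting the grid. The grid report exports a numeric OR matrix and
a classification matrix (the heatmap's numeric twin); no plot rendering is
bundled.

## Synthetic data

`simulate_pair` draws true effects γ_j ~ N(0.15, 0.05²), pleiotropy
α_j = 0 (`none`), ~N(0, τ²) (`balanced`), or ~N(μ_α, τ²) (`directional`),
optionally scales a fraction of α_j by `outlier_scale` (silent α_j are
given a unit effect first so "none"-mode outliers exist), sets
Γ_j = β·γ_j + α_j, and adds sampling noise at SEs implied by allele
frequencies f ~ U(0.05, 0.5) and the sample sizes: σ_X² = 1/(2f(1−f)N_exp)
for the standardized exposure and, for the binary outcome, the
effective-sample-size approximation σ_Y² = 1/(N_out·v·2f(1−f)) with case
fraction v. Defaults mirror the emulated study scale: k = 30,
N_exp = 8,293, N_out = 456,348, v = 0.02 — chosen so simulated instruments
clear genome-wide significance and Wald-ratio SEs land near the worked
examples'. Alleles are drawn from non-palindromic pairs so default
harmonization keeps every SNP; LD blocks are emitted as an r² table (no
individual-level genotypes or realistic genome-wide LD maps). The truth
record retains every latent quantity. What the generator does **not**
emulate: real LD structure, allele-frequency spectra, winner's-curse bias
in instrument selection, sample overlap, or population stratification —
so passing calibration tests demonstrates estimator correctness under the
assumed model, not robustness to those real-data complications.

The fixture pairs reconstruct the per-SNP rows of the two published worked
examples (16 SNPs for IL-18 → acute myeloid leukemia, 2 for IL-17 →
stomach cancer) from their printed ORs and 95% CIs: θ = ln OR,
se = (ln CI_hi − ln CI_lo)/(2·1.95996). Only the ratio scale is
recoverable from print, so fixture instruments carry γ = 1 with a
negligible exposure SE; this is sufficient for IVW, the weighted median,
the likelihood method, PRESSO and leave-one-out, but not for Egger (which
needs spread in γ) — Egger is validated on synthetic data instead.
Because the printed inputs are rounded to 2 decimals, combined estimates
carry a ±0.02–0.03 tolerance on the OR scale, and the reconstructed CI
bounds round-trip the printed ones only up to the print's own asymmetry
(≤ ~6% relative for bounds as small as 0.05). One fixture row (rs7601267,
OR 1.06, CI 0.33–3.56, printed p 0.029) is internally inconsistent — the
CI spans 1 — and the fixture keeps the OR/CI and ignores that p.

## Numerical conventions and edge cases

γ = 0 raises an undefined-ratio error; empty instrument sets are explicit
errors at the estimator layer and `not_testable` at the pipeline layer;
total R² ≥ 1 is a validation error; Q with k < 2 is not applicable;
excluding every instrument is an error. All Monte-Carlo stages take
explicit integer seeds and are bit-reproducible.

## Problem sizes used in the validation suite

Calibration checks run at desk scale: 500 replicates (k = 30) for IVW
bias/coverage, 200 datasets (k = 10, n_sim = 1000) for PRESSO null
calibration, 40 seeded runs for 10σ-outlier detection, and 120 replicates
per mode for Egger intercept calibration. The full published 27×20
cytokine–cancer grid requires the original Finnish and UK Biobank summary
statistics and is out of scope; the grid machinery is exercised on 2×2
synthetic grids with injected effects instead.
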