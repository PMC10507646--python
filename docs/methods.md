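# Methods

## Setting and assumptions

summarymr implements two-sample Mendelian randomization on summary
statistics: per-SNP associations with an exposure come from one GWAS and
per-SNP associations with an outcome from another, with no individual-level
data. A SNP is a valid instrument when it is (1) associated with the
exposure, (2) independent of exposure–outcome confounders, and (3) affects
the outcome only through the exposure. Violations of (3) — horizontal
pleiotropy — are the central practical threat, and the sensitivity battery
exists to detect and mitigate them.

All p-values in the package use the normal approximation z = β/SE (two-sided)
and are floored at 1e-300 to avoid underflow; all 95% intervals use
z = 1.959964.

## Estimators

Per-SNP Wald ratios θ̂_j = β̂_Yj/β̂_Xj carry first-order standard errors
σ_j = σ_Yj/|β̂_Xj| by default; a second-order delta-method SE
√(σ_Yj²/β̂_Xj² + β̂_Yj²σ_Xj²/β̂_Xj⁴) is available via `se_order="second"`.
First-order weights treat the exposure betas as known, which is the
convention of the widely used MR tooling and is accurate when instruments
are strong (F ≫ 10); with the default synthetic generator the SE
understatement is ≈ 3%.

- **IVW fixed**: inverse-variance weighted mean of the ratios; identical to
  the weighted least-squares slope through the origin of β̂_Y on β̂_X with
  weights 1/σ_Yj² (asserted to 1e-10 against an independent WLS
  implementation in the tests).
- **IVW random**: the multiplicative random-effects variant — same point
  estimate, SE scaled by max(1, √(Q/(J−1))). The floor at 1 keeps
  fixed ≡ random under homogeneity and never rewards under-dispersion. The
  additive (DerSimonian–Laird) model is deliberately not used, matching the
  convention of the summary-data MR tools this package interoperates with.
- **MR-Egger**: weighted LS of β̂_Y on β̂_X with free intercept, weights
  1/σ_Yj². Inputs are first oriented so every β̂_Xj ≥ 0 (joint sign flip of
  each pair, which leaves ratios unchanged); without this the intercept is
  not identified consistently. Coefficient SEs use the WLS covariance scaled
  by max(1, √(RSS_w/(J−2))). Requires J ≥ 3 and nonzero spread in β̂_X.
- **Weighted median**: ratios are sorted, normalized weights accumulated as
  midpoint scores s_j = Σ_{k≤j} w'_k − w'_j/2, and the estimate is the
  linear interpolation of θ̂ against s at s = ½ (clamped to the extreme
  ratios outside [s_1, s_J]). The SE is a parametric bootstrap: each of
  `n_boot` (default 1000) replicates redraws θ_j* ~ N(θ̂_j, σ_j²) and
  recomputes the median; the SE is the replicate standard deviation,
  seeded. An analytic SE exists in the literature; the bootstrap was chosen
  as the more common convention and is flagged as such.

## Sensitivity battery

- **Cochran's Q** = Σ w_j (θ̂_j − θ̂_IVW)² with first-order weights,
  referred to χ² on J−1 degrees of freedom. First-order weights keep Q
  consistent with the IVW default; modified-Q variants are out of scope.
- **Egger intercept test**: directional pleiotropy is declared when the
  intercept p is strictly below 0.05.
- **MR-PRESSO**: the observed weighted residual sum of squares
  RSS = Σ_j (β̂_Yj − θ̂^{(−j)}β̂_Xj)²/σ_Yj², where θ̂^{(−j)} is the IVW
  estimate excluding SNP j, is compared against `n_sim` (default 1000)
  replicates with β_Yj* ~ N(θ̂^{(−j)}β̂_Xj, σ_Yj²) and exposure betas held
  fixed. The global p is the exceedance fraction, reported as a bound
  "< 1/n_sim" at zero exceedances. Per-SNP exceedance fractions,
  Bonferroni-corrected by J, flag outliers at `outlier_alpha` (default
  0.05). The corrected estimate is fixed-effect IVW on the non-outliers, and
  the distortion test compares the resulting shift against the shift from
  removing equally many SNPs at random (1000 draws). MR-PRESSO requires
  J ≥ 4; below that the pipeline falls back to Q and the Egger intercept.
  The pipeline removes PRESSO outliers *before* the headline estimates, so
  reported sensitivity rows are outliers-corrected.
- **Leave-one-out**: fixed-effect IVW J times excluding one SNP each, plus
  the full-panel entry; `loo_sign_consistency` summarizes whether every LOO
  interval excludes the null on the same side as the full estimate.

## Instrument selection

Selection keeps SNPs with exposure p strictly below the threshold (default
5e-7, the conventional relaxed genome-wide level used when the strict 5e-8
yields too few instruments). Clumping is greedy by ascending p (ties broken
on chromosome, position, then rsID so results are input-order invariant):
each index SNP removes unclaimed SNPs on the same chromosome within the
window (default 10,000 kb) with r² ≥ the threshold (default 0.001). LD comes
from an explicit SNP-labelled matrix — generated or user-supplied — rather
than a remote reference panel; missing pairs count as r² = 0 with a warning.
This makes clumping deterministic and offline at the cost of requiring the
caller to provide LD when it matters.

Instrument strength uses F = R²(N−2)/(1−R²). Because summary files rarely
state the R² behind each SNP, two routes are offered and logged: per-SNP
R² = 2·EAF·(1−EAF)·β² (variance explained assuming a unit-variance
exposure), or a single caller-supplied aggregate R². Neither is asserted as
"the" definition; both are conventional. SNPs with F < 10 trigger a warning
but are not removed (weak-instrument screening is the caller's decision).
The optional screen for instruments directly associated with the outcome is
off by default, since no universal threshold exists for it.

## Harmonization

One strict tab-delimited dialect (columns SNP, chr, pos, effect_allele,
other_allele, eaf, beta, se, pval, n; "." for missing; C-locale numbers;
17-significant-digit floats so read∘write is the identity). Harmonization
aligns outcome records to the exposure's effect allele: identical labels pass
through; swapped labels flip the outcome beta and complement its EAF; strand
relabellings (A↔T, C↔G) are attempted before declaring a pair incompatible.
Palindromic SNPs (A/T, G/C) are resolved by allele frequency: dropped when
either side's EAF is within 0.08 of 0.5 (the conventional [0.42, 0.58]
ambiguity window) or missing; otherwise same-side frequencies mean aligned
strands and opposite sides imply a flip. Every shared SNP appears exactly
once in the output with an explicit status, so attrition is auditable.

## Synthetic generator

`simulate_summary_stats` draws true exposure effects β_Xj ~ N(mean, sd²),
observes them with noise (σ_X), and builds outcome effects
β̂_Yj = θ·β_Xj + α_j + N(0, σ_Y²), where α_j = 0 for valid instruments and
α_j ~ N(pleiotropy mean, sd²) for the invalid fraction (mean forced to 0
when `balanced_flag` is set, so InSIDE holds under balanced pleiotropy and
fails directionally otherwise). P-values come from the same normal
approximation the selection stage uses. Variants sit on one synthetic
chromosome at 100 kb spacing with EAF uniform on `eaf_range` and a
configurable palindromic fraction; LD is block-diagonal by construction.

Defaults were chosen once as a realistic strong-instrument scenario:
16 SNPs (a typical small panel for an environmental exposure), exposure
effects N(0.05, 0.01²) with σ_X = 0.005 and σ_Y = 0.01 (per-SNP F ≈ 100,
comfortably past the weak-instrument bound), biobank-scale sample sizes
(423,796 exposure / 400,000 outcome), EAF ∈ (0.1, 0.9), 10% palindromic
variants. The directional-pleiotropy stress scenario used in the tests sets
30% invalid instruments with α ~ N(0.02, 0.01²) — a mean direct effect
around 40% of the median per-SNP exposure effect, a moderate-to-strong
exclusion violation.

What the generator does **not** emulate: realistic allele-frequency spectra,
winner's curse in instrument discovery, sample overlap between the two
GWASs, LD-induced correlation between ratio estimates, or binary-outcome
non-collapsibility. Passing tests therefore demonstrate correctness of the
estimators and procedures under the stated structural model, not robustness
to those real-data complications.

## Numerical and design choices

- Strict "<" at the p-threshold; "≥" at the clump r² threshold; window as
  |Δpos| ≤ window_kb·1000 on the same chromosome.
- Per-pair seeds in a study derive deterministically from the study seed, so
  reruns are byte-identical including MR-PRESSO and bootstrap results.
- One pair's failure (no instruments, no overlap, unreadable outcome file)
  marks that pair failed and never aborts the study; the CLI signals partial
  failure with exit code 2.
- The report annotates both the raw 0.05 significance rule and a
  Bonferroni-by-outcome-count interpretation without committing to either;
  the distinction between "significant" and "suggestive" findings is left to
  the caller.
- Test problem sizes (replicate counts of 100–500, n_sim of 300–500) were
  picked so the binomial bands being asserted are meaningfully narrow while
  the whole suite stays fast.

## Known limitations

- First-order ratio SEs ignore exposure-side noise; with weak instruments
  (F near 10) coverage will dip below nominal. Use `se_order="second"` or
  stronger instruments.
- The MR-PRESSO distortion test uses the original resampling scheme, which
  is known to be conservative for small outlier counts.
- With one injected +10σ_Y outlier among J instruments, the IVW shift it
  causes is ≈ 10/√J standard errors of the corrected estimate, so for
  J = 20 the corrected estimate beats the contaminated one in only ≈ 87% of
  replicates — outlier removal reliably de-biases, but cannot beat the
  contaminated estimate almost surely at this outlier size.
- Steiger directionality filtering, mode-based estimators, multivariable MR
  and proxy-SNP lookup are out of scope.
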