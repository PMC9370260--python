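# Methods

## Model and estimands

All computations operate on summary-level per-SNP associations from two
non-overlapping GWAS samples: exposure effects β̂_Xj ~ N(γ_j, σ_Xj²) and
outcome effects β̂_Yj ~ N(θγ_j + α_j, σ_Yj²), where θ is the causal effect of
one exposure unit on the outcome's log odds, γ_j the SNP's true effect on the
exposure, and α_j a direct (horizontally pleiotropic) effect on the outcome.
Valid instruments have α_j = 0; the estimators differ in which departures
from that they tolerate. Estimation error in β̂_Xj is ignored by the
ratio-based estimators (the standard "NOME" first-order approximation,
accurate for strong instruments, F ≫ 10) and modeled explicitly by the
maximum-likelihood estimator.

### Estimators

- **Wald ratio** (1 SNP): θ̂ = β̂_Y/β̂_X, SE = σ_Y/|β̂_X|.
- **IVW**: inverse-variance weighted mean of the ratios with weights
  w_j = (β̂_Xj/σ_Yj)². Fixed-effect SE (Σw)^(−1/2); the multiplicative
  random-effects model inflates it by max(1, √(Q/(J−1))) — the convention of
  the widely used MR software this pipeline mirrors — so random effects never
  report a smaller SE than fixed.
- **Maximum likelihood**: profiles the per-SNP nuisance means out of the
  joint normal likelihood, leaving −2ℓ(θ) = Σ (β̂_Yj − θβ̂_Xj)²/(σ_Yj² +
  θ²σ_Xj²), minimized from the IVW start by a bounded scalar search (width
  widened ×10 per restart, up to 5 restarts). The SE comes from the numerical
  curvature of the profile likelihood at the optimum (central differences,
  step 10⁻³ of the IVW SE), which is the correct observed information for θ
  in the presence of the profiled nuisances.
- **MR-Egger**: each SNP is oriented so β̂_Xj > 0 (both effects negated
  otherwise — required for the intercept to be interpretable, since allele
  labels carry no direction), then β̂_Y is regressed on β̂_X by weighted
  least squares (weights σ_Yj⁻², free intercept). The slope estimates θ under
  the InSIDE assumption; the intercept and its t(J−2) test measure
  directional pleiotropy. Analytic SEs use the WLS residual variance with
  t(J−2) inference; the optional residual bootstrap resamples standardized
  weighted residuals and reports the SD over refits (normal inference), with
  both SEs retained side by side. Exposure effects with (near-)zero spread
  after orientation raise a collinearity error rather than returning an
  unidentified slope.
- **Weighted median**: ratios sorted ascending (ties broken by a stable
  pre-sort on SNP id), weights normalized, and the estimate interpolated
  linearly in cumulative weight S_j = Σ_{k≤j} w'_k − w'_j/2 at S = 0.5.
  The SE is the SD over parametric-bootstrap resamples of (β̂_Xj, β̂_Yj),
  with weights recomputed inside each resample.
- **Penalized weighted median**: per-SNP heterogeneity Q_j = w_j(θ̂_j −
  θ̂_WM)² against the plain weighted median, one-sided p_j from χ²(1), and
  penalized weights w_j·min(1, penalty·p_j) before re-taking the median.
  Penalty default 20, the constant of the original penalized estimator.
- **MR-PRESSO**: observed RSS = Σ w_j(θ̂_j − θ̂_(−j))² with leave-one-out
  IVW estimates θ̂_(−j); a parametric null (β̂*_X ~ N(β̂_X, σ_X²),
  β̂*_Y ~ N(θ̂_(−j)β̂_X, σ_Y²)) yields the global empirical p with the +1
  correction, so p ≥ 1/(n_sim+1) and is never zero. When global p < 0.05,
  per-SNP residuals are compared to their simulated distributions,
  Bonferroni-adjusted across J, and flagged below α = 0.05; the corrected
  estimate is plain fixed-effect IVW on the retained set. The distortion test
  (displacement vs removing equally many random SNPs) is reported but gates
  nothing.

### Decision tree and meta-analysis

Per cohort: J = 1 → Wald ratio; J = 2 → IVW + maximum likelihood; J ≥ 3 →
plus Egger and both medians; J ≥ 4 → plus MR-PRESSO. The Egger intercept
test (p < 0.05) promotes Egger to primary, else IVW; Cochran's Q (p < 0.05)
selects random- over fixed-effect IVW. Cohort log-ORs are combined by
inverse-variance meta-analysis; the cross-cohort heterogeneity gate (same
threshold) switches to DerSimonian–Laird additive-τ² random effects. Combined
p-values are tiered: < 0.01 significant (Bonferroni, five outcome diseases),
0.01–0.05 suggestive, otherwise null. Every gate outcome is appended to a
decision trace so no reported number rests on a silent choice.

When a cohort is only available as a printed OR with symmetric 95% CI, the
log-OR and SE are reconstructed as β = ln(OR), SE = [ln(hi) − ln(lo)]/(2z)
with z = 1.959964 (not 1.96 — the difference reaches the third decimal of
reconstructed SEs); a >1% relative mismatch when mapping back to the printed
bounds triggers a warning, since asymmetric (e.g. profile-likelihood)
intervals are not faithfully represented by this normal approximation.

## Harmonization

Records are joined on SNP id (duplicates keep the smallest p-value, with a
warning). Swapped alleles negate the outcome beta; strand-complemented pairs
are treated as the same variant reported on the other strand. Palindromic
(A/T, C/G) variants are resolved by effect-allele frequency: kept only when
both EAFs are present and outside [0.5 − w, 0.5 + w] (default w = 0.08,
configurable; a common choice in two-sample MR practice, not a published
constant), sign-flipped when the frequencies sit on opposite sides of 0.5,
dropped otherwise — including when either EAF is missing (conservative).
Proxy variants for SNPs absent from the outcome GWAS are accepted as a
user-supplied two-column table; no LD-server lookup is performed. Variant
matching is by identifier only (no positional matching), and clumping uses
user-supplied positions and pairwise r² rather than a bundled reference
panel, falling back to the distance rule alone when r² is unknown.

## Tunable parameters

| parameter | default | rationale |
|---|---|---|
| p-value threshold | 5×10⁻⁸ (absolute) / 1×10⁻⁵ (metabolite) | genome-wide significance; relaxed for metabolite GWAS with small n |
| clumping | r² ≤ 0.001 within 10,000 kb | near-independent instruments |
| F filter | F > 10, strict | weak-instrument convention |
| palindromic EAF window | 0.08 | drop when EAF ∈ [0.42, 0.58] |
| pleiotropy / heterogeneity gates | 0.05 | nominal test level |
| median bootstrap reps | 5,000 | SE Monte-Carlo error ≈ 1% |
| Egger bootstrap reps | 1,000 | intercept/slope SD stabilizes |
| PRESSO n_sim | 1,000 | empirical p resolution 10⁻³ |
| PRESSO outlier α | 0.05 Bonferroni-adjusted across J | familywise control per instrument set |
| penalty constant | 20 | original penalized-median convention |
| significance tiers | 0.01 / 0.05 | Bonferroni over five outcomes |

The pipeline's `p_threshold` defaults to `None`, meaning the exposure file is
treated as an already-selected instrument set (the common situation where
instruments are taken from a published GWAS); only the F filter is applied.
Set it explicitly to screen a full summary-statistics file.

## Synthetic data generator

The generator emulates the post-clumping regime of antioxidant-exposure /
cancer-outcome MR studies: 2–27 independent strong instruments, exposure GWAS
of 441–110k samples explaining ~1.7–30% of variance, and biobank-scale binary
outcome GWAS with low case fractions. Defaults are
ascorbate-on-colon-cancer-like: 10 SNPs, R² = 1.7%, n_exp = 52,018,
n_out = 420,531, case fraction 0.894%, θ = −0.25.

Concretely: MAFs uniform on (0.1, 0.5); per-SNP R² shares heterogeneous (half
the total split equally as a floor, half by a flat Dirichlet draw) to mimic a
lead SNP plus secondary hits — near-equal instrument strengths are the regime
in which the Egger slope is weakly identified, and real instrument sets are
not like that; γ_j sized from the shares; σ_Xj = [2·MAF(1−MAF)·n_exp]^(−1/2)
and σ_Yj = [2·MAF(1−MAF)·n_out·cf(1−cf)]^(−1/2), the standard large-sample
variance approximations for a standardized quantitative trait and a
log-odds-scale binary trait. Pleiotropy modes: none, balanced (mean-zero),
directional, and InSIDE-violating (direct effects correlated with instrument
strength, ρ default 0.5). Directional and InSIDE-violating direct effects are
defined relative to the exposure-increasing allele — the only frame in which
"directional" is meaningful, since reported allele labels are arbitrary. An
optional implanted outlier shifts one SNP's outcome effect by a chosen number
of its own ratio SEs. A configurable fraction of outcome rows is reported on
the swapped allele (default 50%) and a fraction of variants can be made
palindromic, exercising harmonization end to end. The multi-cohort variant
reuses one set of variants, true effects, and pleiotropy across outcome
cohorts, varying only sampling noise and allele orientation.

What the generator does **not** emulate: LD between instruments (the
post-clumping assumption is independence), winner's-curse inflation of the
discovery effect sizes, sample overlap between exposure and outcome GWAS,
population stratification, and genuinely asymmetric ratio distributions.
Passing calibration tests therefore demonstrates correctness of the
estimators under their stated model, not robustness to those additional
real-data pathologies.

## Numerical choices

- Confidence intervals use z = 1.959964 throughout.
- p-values are floored at 10⁻³⁰⁰ to stay in (0, 1]; empirical (resampling)
  p-values use the +1 correction.
- All resampling (bootstraps, PRESSO null, generator) uses
  `numpy.random.default_rng(seed)`; identical seeds give bit-identical
  results, and rescaling the exposure by c rescales bootstrap replicates by
  exactly c (the underlying standard normals are shared).
- Weighted-median ties in θ̂_j are broken by a stable sort on SNP id, making
  the estimate independent of input row order.
- Bootstrap exposure draws that land exactly on zero are nudged to 10⁻³⁰⁰;
  their ratio weight is then ~0, so the median is unaffected.
- Greedy clumping visits candidates by (p-value, SNP id), so output is
  deterministic and row-order invariant.
- I² is clamped at 0; Q of a homogeneous set reports p = 1.

## Known limitations

- The weighted-median parametric bootstrap (resamples centered at the
  observed per-SNP estimates, the field convention) is conservative: the
  resampled ratio centers are already dispersed by sampling noise, which
  flattens the density at the median and inflates the SE by ~10–15% in the
  10–27 SNP regimes. Null rejection rates land near 0.025–0.030 at nominal
  0.05. Inference from the medians is therefore slightly conservative, never
  anti-conservative.
- MR-Egger is weakly identified when instrument strengths are nearly equal
  (collinearity error in the exact-equality limit) and its slope SE in
  rare-disease outcome GWAS can exceed the pleiotropy bias it corrects;
  the pipeline reports it alongside IVW rather than replacing it unless the
  intercept test fires.
- PRESSO outlier correction removes flagged SNPs and refits; when the outlier
  carries little weight, removal can occasionally move the estimate away from
  truth (probability ≈ 1 − Φ(k√f/2) for a k-ratio-SE outlier with weight
  fraction f).
- Reconstruction from printed OR/CI assumes a symmetric normal interval on
  the log scale and inherits the print precision of its inputs.
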