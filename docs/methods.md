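# Methods

## Summary-level model

Each instrument j carries an exposure association β_Xj (SD units of
circulating GDF-15 per effect allele) and an outcome association β_Yj
(log-odds of gallstone disease per effect allele). Under the instrumental-
variable assumptions the Wald ratio θ_j = β_Yj/β_Xj estimates the causal
log-OR per SD of exposure; we use the first-order standard error
se(θ_j) = se(β_Yj)/|β_Xj|, which ignores uncertainty in β_Xj. That is
adequate here because the instruments are strong (the weakest has
β_X/se = 5.9) and it is the convention the published estimates follow —
second-order terms change nothing at the reported precision.

### Harmonization

Outcome records are located by rsID, or through a user-supplied
original→proxy map (the FinnGen outcome uses rs118170439 for rs112253475,
r² = 0.8; the proxy's statistics are used unchanged, with r² kept as
metadata only). Alleles are aligned by label, with sign flip and EAF
reflection when effect/other are swapped, and strand complementation when
labels match only on the opposite strand. Palindromic SNPs (A/T, G/C)
cannot be strand-resolved from labels; they are dropped only when the
exposure EAF lies in [0.5−w, 0.5+w] (default w = 0.08), i.e. when the
frequency carries no strand information. This window keeps rs2517481
(G/C, EAF 0.59) in the analysis, as the source analysis did. A palindromic
SNP with no EAF at all is always dropped; an irreconcilable allele pair
gets an explicit error status, never silence.

### Estimators

* **IVW.** Weighted mean of Wald ratios, w_j = 1/se(θ_j)². Random effects
  are multiplicative: the fixed-effect SE is inflated by
  max(1, sqrt(Q/(L−1))) where Q is Cochran's statistic. The floor at 1
  means homogeneity can never *shrink* the SE. Additive (DerSimonian–Laird)
  random effects were deliberately not used: the multiplicative form is
  what reproduces the published UK Biobank interval (1.01, 1.29) from the
  per-SNP table. P-values are two-sided normal; CIs are ±1.96·SE.
* **MR-Egger.** Instruments are oriented so every β_X > 0, then β_Y is
  regressed on β_X by WLS (weights 1/se(β_Y)²) with a free intercept.
  Standard errors are scaled by max(1, σ̂), σ̂² = RSS_w/(L−2); the slope
  and intercept p-values use t(L−2) while CIs use ±1.96·SE. This
  asymmetric convention is intentional — it mirrors the widely used R
  implementation and jointly reproduces the published "1.23 (1.01, 1.49),
  p = 0.176" row from the table inputs (our computed slope OR is 1.222;
  the 0.008 gap comes from the inputs being printed to 3 decimals).
* **Weighted median.** Ratios are ordered; with normalized weights w′ the
  j-th ratio sits at cumulative position p_j = Σ_{k≤j} w′_k − w′_j/2, and
  the estimate linearly interpolates θ at p = 0.5. The SE is the standard
  deviation of the estimate over 1000 parametric redraws
  θ*_j ~ N(θ_j, se(θ_j)); the bootstrap is explicitly seeded and affects
  only the SE, never the point estimate. Note the interpolated estimate is
  a smoothed version of the L1-objective median: it lies in the same
  inter-atom bracket as argmin Σ w_j|θ_j − m| but generally not on an atom.
* **MR-PRESSO.** The observed statistic is RSS_obs = Σ_j w_Yj
  (β_Yj − θ̂_(−j)β_Xj)², with θ̂_(−j) the leave-one-out IVW estimate and
  w_Yj = 1/se(β_Yj)². Its null distribution is simulated by redrawing
  β*_Yj ~ N(θ̂_(−j)β_Xj, se(β_Yj)) and recomputing the statistic —
  including re-estimating the leave-one-out means — n_sim times (default
  1000; the source analysis does not state its count, so this default is
  prominent and configurable). Empirical p-values use (1+k)/(n_sim+1), so
  the attainable floor is 1/(n_sim+1) and p is never zero. Per-SNP outlier
  p-values compare each SNP's weighted squared residual with its own
  simulated distribution, Bonferroni-adjusted by L. The distortion test
  compares the raw-minus-corrected shift against the shift from removing
  equally many instruments at random; it is reported for completeness but
  not used for decisions. Instruments are sorted by rsID before any draw,
  so results are bit-identical for a given seed regardless of input order.
* **Ties and determinism.** All estimators sort instruments by rsID
  internally; rsIDs are unique within a dataset, so ordering is total and
  every output is reproducible bit-for-bit under a fixed seed.

### Meta-analysis and power

The two cohorts are combined at the study level (pooling their IVW
estimates, not their instrument-level data): weights 1/se², pooled SE
(Σw)^(−1/2), between-study Q reported. Study SEs may be back-derived from
published CIs via (ln hi − ln lo)/(2·1.96); with the published ORs this
pooling gives 1.09 (1.04, 1.15), matching the published pooled estimate —
which is why study-level pooling was adopted. Power for a binary outcome
uses Φ(√(N·r²·K(1−K))·|ln OR| − z_{1−α/2}), the standard normal
approximation; with the diabetic subgroup's N = 26,100, K = 2,573/26,100,
r² = 0.084 and OR 1.06 it gives 12.6%, i.e. the published "13%".

## Individual-level model

The per-SD polygenic score is Σ_j β_Xj·dosage_ij, standardized to mean 0,
SD 1. Logistic models are fitted by maximum likelihood (Newton), with
covariate sets nested Model 1 ⊂ 2 ⊂ 3; missing covariates are handled by
complete-case analysis with the dropped-row count reported. Separation and
non-convergence raise explicit fit-failure errors.

Nonlinearity uses Harrell's restricted cubic basis: k−1 columns, identity
plus truncated cubics constrained to linearity beyond the boundary knots,
knots at the (0.10, 0.50, 0.90) score quantiles for k = 3 (0.05/0.35/0.65/
0.95 for 4; 0.05/0.275/0.50/0.725/0.95 for 5). The default is k = 3 — the
smallest basis that can express a U while keeping a single identifiable
turning point. The nonlinearity p-value is the likelihood-ratio test of
the k−2 nonlinear coefficients jointly zero (preferred over Wald for its
small-coefficient behaviour; the choice is recorded in the fit object).
The **turning point** is the argmin of the fitted partial log-odds (PRS
terms only) on a grid at 0.001·SD resolution, ties broken toward the
smaller score; the knot list is always reported alongside, since a
quantile knot is the other reading of a published "turning point". A
fitted curve spanning < 0.01 log-odds is flagged flat — its argmin is
reported but not meaningful. Stratified estimation splits at the turning
point (low: PRS < cutoff) and refits the linear model per side, for the
overall, nondiabetic and diabetic strata; an empty side is an error, which
is exactly what happens when the fitted curve is monotone and the argmin
sits on the boundary — a linear association gives no meaningful split.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, not any real
person: Hardy–Weinberg Binomial(2, EAF) dosages with no LD; a latent
exposure Σβ_j·dosage + optional shared confounder + Gaussian noise with
SD √(1 − Σ2p(1−p)β²) so the exposure has unit variance; covariates from
simple parametric models matched to the published cohort means (age
N(57, 8) truncated 40–70, 54% female, BMI N(27.4, 4.8), standard-normal
PCs and deprivation, LDL N(3.57, 0.9), HbA1c N(35.95, 6.5), smoking 10%);
diabetes correlated with BMI (logit slope 0.1 per kg/m², intercept solved
for prevalence 0.077) and metformin concentrated in diabetics (30% vs
0.4%). Outcome models are logistic with the intercept solved numerically
(Brent) to hit the target prevalence — 0.049 for gallstones, 0.0061 for
the diabetic-complications positive control (generated with a protective
per-SD OR of 0.77).

Defaults are the published study conditions: EAFs 0.59/0.14/0.92/0.98 and
effects 0.059/0.370/0.160/0.270 for the four instruments, per-SD OR 1.11,
U-shape vertex −0.06. The U-shape curvature (0.12 per squared PRS SD) is
derived from the published stratified estimates: low/high per-SD ORs of
0.78 and 1.28 imply |d logit/dPRS| ≈ 0.25 at |PRS − v| ≈ 1, hence a
quadratic coefficient of about 0.12.

**Causal-effect scale.** `causal_or_per_sd` acts per SD of the genetic
score (the PRS), matching how the individual-level estimates are reported.
The summary-level IVW instead estimates the effect per SD of the measured
exposure; under this generative model the two differ by the factor
sd(genetic score) = √(Σ2p(1−p)β²) ≈ 0.203 for the default instruments, so
the IVW's target is ln(causal_or_per_sd)/0.203. The recovery tests use
that implied value. (The two scales happen to give numerically similar ORs
in the published analysis; they are conceptually distinct.)

**Extended instrument configuration.** The four-instrument score takes
only 81 distinct values and one SNP carries most of the variance, so the
score distribution is coarse: a spline turning point is identified only up
to cluster spacing, and Egger/PRESSO power studies need more instruments.
`extended_config` draws 30 (configurable) moderate-frequency instruments
deterministically, giving a quasi-continuous score; property tests that
need vertex localization or pleiotropy power use it, while everything
keyed to the published numbers uses the four-instrument default. Even with
a continuous score the 3-knot spline's argmin for the default quadratic
sits asymptotically at −0.029 rather than −0.06 — a basis-approximation
bias of +0.03 that is inherent to estimating a vertex with one nonlinear
degree of freedom, and within the ±0.05 localization the tests require.

## Problem sizes and numerical choices

Recovery and calibration tests run at sizes chosen to make their Monte
Carlo error small relative to the asserted tolerance: per-SD OR recovery
averages three cohorts of n = 200,000 (single-cohort sampling SE ≈ 0.021
on the log scale); end-to-end IVW bias is the mean error over 30 cohorts
of n = 500,000; spline type-I calibration uses 200 cohorts of n = 20,000
(the LR test's null calibration is size-insensitive at these scales);
turning-point localization uses 10 cohorts of n = 300,000. All test seeds
are fixed, so every reported rate is reproducible exactly. The power
formula's Monte-Carlo cross-check tolerates four MC standard errors at
10⁶ draws (≈1.3×10⁻³) — the closed form and a simulated rejection rate
cannot agree more tightly than the simulation's own noise.

Normal quantile 1.96 is used for all reported CIs (matching the published
precision); t quantiles are used only for Egger p-values as described.
The logit intercept solver brackets [−40, 40] and raises if the target
prevalence is unreachable. Grid argmins break ties toward the smaller
score by taking the first minimum on an ascending grid.

## What the synthetic tests do and do not show

Passing recovery tests show the estimators are correct under the stated
generative model: independent HWE genotypes, logistic outcomes, covariates
independent of genotype (so adjustment is variance-only), no LD, no
population structure beyond independent PC columns, and pleiotropy only of
the explicitly injected kind. They do not validate ICD-based phenotyping,
genotype QC, relatedness handling, or the behaviour of the score under LD
— all deliberately out of scope. The embedded instrument table reproduces
the published summary-level results to printed precision with two known
exceptions, both documented in the reproduction report: the published
sensitivity table's Q and Egger-intercept cells match only under a
cohort-label exchange (the rows appear transposed at source), and the
published instrument r² (~8.4%) is not derivable from the printed table
(2p(1−p)β² gives 4.1%); both are flagged, not forced. One published CI
(FinnGen IVW 1.02–1.14) is narrower than any interval derivable from the
printed per-SNP inputs, so only the FinnGen point estimate is compared,
and one published bound (the high-group Model-3 CI "1.28 (1.90, 1.43)")
is arithmetically impossible and excluded from comparison surfaces.

## Limitations

First-order Wald SEs only; no mode-based or multivariable estimators; no
LD-aware clumping or reference panels (instruments are taken as given);
fixed-effect meta-analysis only (between-study Q is reported but not used
to inflate); the synthetic diabetes/metformin structure is a caricature
sufficient for stratified-analysis plumbing, not an endocrinological
model; and the turning-point estimator inherits the restricted-cubic
basis's vertex bias described above.
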