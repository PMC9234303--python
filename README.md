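# gdf15mr

Causal-inference toolkit for the question: **does genetically predicted
circulating GDF-15 (growth differentiation factor 15) raise the risk of
gallstone disease?** GDF-15 is the leading biomarker of metformin use and a
candidate therapeutic target for diabetic complications, so an adverse
effect on gallstones matters clinically. The package is written for
epidemiologists and biostatisticians who want the whole pipeline — from
GWAS summary statistics to nonlinear individual-level dose–response — as a
tested, reusable Python library.

## What it implements

**Two-sample Mendelian randomization.** With L genetic instruments, each
SNP j contributes a Wald ratio θ̂ⱼ = β̂_Yj / β̂_Xj with first-order
se(θ̂ⱼ) = se(β̂_Yj)/|β̂_Xj|. The main estimator is inverse-variance
weighted pooling with multiplicative random effects,

    θ̂ = Σ wⱼθ̂ⱼ / Σ wⱼ,  wⱼ = se(θ̂ⱼ)⁻²,
    se(θ̂) = (Σ wⱼ)^(-1/2) · max(1, √(Q/(L−1))),

where Q is Cochran's heterogeneity statistic. Sensitivity analyses:
MR-Egger weighted regression with a free intercept (the intercept is the
directional-pleiotropy test), the cumulative-weight interpolated weighted
median with a parametric-bootstrap SE, MR-PRESSO's simulation-based
global/outlier/distortion tests, and leave-one-out re-estimation. Summary
statistics are harmonized to a common effect allele first (sign flips,
strand complementation, frequency-based handling of palindromic SNPs,
linkage-proxy substitution). The four published GDF-15 instruments and
their gallstone associations in UK Biobank and FinnGen ship as an embedded
dataset (`reference_instruments`), so the whole summary-level analysis runs
with no downloads.

**Meta-analysis and power.** Fixed-effect inverse-variance pooling of
study-level log-ORs, and the normal-approximation power of a binary-outcome
MR test, Φ(√(N·r²·K(1−K))·|ln OR| − z₀.₉₇₅).

**Polygenic risk score stage.** A weighted allele score (per-SD
standardized), logistic models at three adjustment levels (unadjusted;
+age, sex, BMI, 20 genetic PCs; +deprivation, smoking, drinking, physical
activity, LDL-C, glucose, HbA1c, metformin), a 3-knot restricted cubic
spline (Harrell basis) with a likelihood-ratio nonlinearity test, turning-
point location as the argmin of the fitted partial log-odds, and low/high
stratified re-estimation — overall and by diabetic status. Because
individual-level biobank data cannot be redistributed, a fully seeded
synthetic-cohort generator (`synthetic_data`) reproduces the statistical
structure the analysis assumes and closes the loop simulate → derive
summary statistics → harmonize → estimate.

## Worked example

```python
from gdf15mr import harmonized_reference, ivw, egger, weighted_median

ins = harmonized_reference("ukb")          # 4 instruments, all kept
est = ivw(ins, effects="random")
print(est.or_, est.ci_low, est.ci_high)    # 1.141  1.012  1.287
slope, intercept = egger(ins)
print(slope.or_, intercept.pvalue)         # 1.222  0.473
print(weighted_median(ins, seed=1).or_)    # 1.157
```

Read: one SD higher genetically predicted GDF-15 is associated with 1.14-
fold gallstone odds in UK Biobank (95% CI 1.01–1.29); the Egger intercept
shows no directional pleiotropy; the weighted median agrees (1.16). Running
`python examples/two_sample_mr.py` prints the full table plus Q = 4.68 with
an SE inflation factor of 1.25 and the leave-one-out diagnostic (the pooled
OR falls to 0.91 without rs1227734 — that *GDF15*-region SNP drives the
signal). The other scripts in `examples/` cover meta-analysis + power,
MR-PRESSO outlier removal, end-to-end parameter recovery, and the U-shaped
PRS analysis.

A thin CLI wraps the same functions:

```bash
gdf15mr mr --fixture ukb --seed 1 --out-dir out/
gdf15mr reproduce --out-dir out/          # computed vs published, PASS/FLAG
gdf15mr prs --simulate --n 100000 --seed 7 --out-dir out/
```

## Layout

- `src/gdf15mr/summary_data.py` — GWAS record types, TSV I/O, harmonization, embedded instruments
- `src/gdf15mr/mr_estimators.py` — IVW, Egger, weighted median, Q, leave-one-out
- `src/gdf15mr/mr_presso.py` — MR-PRESSO global / outlier / distortion tests
- `src/gdf15mr/meta_power.py` — fixed-effect meta-analysis, MR power
- `src/gdf15mr/prs_spline.py` — PRS, logistic models, restricted cubic splines, stratification
- `src/gdf15mr/synthetic_data.py` — seeded cohort generator and derived summary statistics
- `src/gdf15mr/reporting.py`, `cli.py` — reproduction report and command-line wrappers
- `docs/methods.md` — modelling assumptions, defaults, numerical choices, limitations
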