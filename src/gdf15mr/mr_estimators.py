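"""Two-sample Mendelian randomization estimators and diagnostics.

Given L harmonized instruments with Wald ratios θ_j = β_Yj/β_Xj and
first-order standard errors se(θ_j) = se_Yj/|β_Xj|, this module provides:

* inverse-variance weighted (IVW) pooling, fixed effects or multiplicative
  random effects (the fixed-effect SE inflated by max(1, sqrt(Q/(L−1)));
* MR-Egger weighted regression with a free intercept — the intercept is the
  directional-pleiotropy diagnostic, the slope the bias-corrected estimate;
* the weighted median of the ordered ratios (cumulative-weight interpolation
  at 50%), consistent when over half the weight comes from valid
  instruments, with a parametric-bootstrap SE;
* Cochran's Q heterogeneity statistic and leave-one-out re-estimation.

All estimates are causal log odds ratios per SD of the exposure and are
reported with exponentiated point estimates and 95% CIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .summary_data import HarmonizedInstrument, kept

__all__ = [
    "MREstimate",
    "InsufficientInstrumentsError",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "leave_one_out",
    "cochran_q",
    "results_table",
]

_Z95 = 1.96  # normal 95% quantile used throughout for reported CIs


class InsufficientInstrumentsError(ValueError):
    """Too few kept instruments for the requested estimator."""


@dataclass(frozen=True)
class MREstimate:
    """A causal estimate (log-OR per SD exposure) with its diagnostics."""

    method: str
    beta: float
    se: float
    pvalue: float
    n_snps: int
    q_stat: float | None = None
    q_pvalue: float | None = None
    scale_factor: float = 1.0

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.beta - _Z95 * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.beta + _Z95 * self.se))


def _arrays(instruments: Iterable[HarmonizedInstrument]):
    ins = kept(instruments)
    # deterministic ordering regardless of caller ordering; ties cannot occur
    # because snp_ids are unique within a dataset
    ins = sorted(ins, key=lambda i: i.snp_id)
    theta = np.array([i.ratio for i in ins], dtype=float)
    se = np.array([i.ratio_se for i in ins], dtype=float)
    if np.any(se <= 0):
        raise ValueError("all ratio standard errors must be positive")
    return ins, theta, se


def wald_ratio(instrument: HarmonizedInstrument) -> MREstimate:
    """Single-instrument causal estimate: the Wald ratio itself."""
    if not instrument.is_kept:
        raise InsufficientInstrumentsError(f"{instrument.snp_id} has status {instrument.status}")
    z = instrument.ratio / instrument.ratio_se
    return MREstimate(
        method="wald_ratio",
        beta=float(instrument.ratio),
        se=float(instrument.ratio_se),
        pvalue=float(2 * stats.norm.sf(abs(z))),
        n_snps=1,
    )


def cochran_q(instruments: Iterable[HarmonizedInstrument]) -> tuple[float, float]:
    """Cochran's Q over the Wald ratios and its χ²(L−1) p-value."""
    _, theta, se = _arrays(instruments)
    L = len(theta)
    if L < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs at least 2 instruments")
    w = 1.0 / se**2
    beta = np.sum(w * theta) / np.sum(w)
    q = float(np.sum(w * (theta - beta) ** 2))
    return q, float(stats.chi2.sf(q, L - 1))


def ivw(instruments: Iterable[HarmonizedInstrument], effects: str = "random") -> MREstimate:
    """Inverse-variance weighted estimate over the Wald ratios.

    With weights w_j = 1/se(θ_j)², the estimate is the weighted mean of the
    θ_j and the fixed-effect SE is (Σw)^(−1/2).  Under ``effects="random"``
    the SE is inflated multiplicatively by max(1, sqrt(Q/(L−1))) — residual
    overdispersion never shrinks it.  P-values are two-sided normal.
    """
    if effects not in ("fixed", "random"):
        raise ValueError(f"effects must be 'fixed' or 'random', got {effects!r}")
    _, theta, se = _arrays(instruments)
    L = len(theta)
    if L < 2:
        raise InsufficientInstrumentsError(
            "IVW needs at least 2 instruments; use wald_ratio for a single SNP"
        )
    w = 1.0 / se**2
    beta = float(np.sum(w * theta) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (theta - beta) ** 2))
    q_p = float(stats.chi2.sf(q, L - 1))
    scale = max(1.0, float(np.sqrt(q / (L - 1)))) if effects == "random" else 1.0
    se_out = se_fixed * scale
    return MREstimate(
        method=f"ivw_{effects}",
        beta=beta,
        se=se_out,
        pvalue=float(2 * stats.norm.sf(abs(beta / se_out))),
        n_snps=L,
        q_stat=q,
        q_pvalue=q_p,
        scale_factor=scale,
    )


def egger(instruments: Iterable[HarmonizedInstrument]) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression: (slope estimate, intercept estimate).

    Instruments are first oriented so every exposure beta is positive (both
    betas negated where needed), then outcome betas are regressed on exposure
    betas by weighted least squares with an intercept, weights 1/se_Yj².
    Standard errors are inflated by max(1, σ̂) where σ̂² = RSS_w/(L−2);
    p-values use the t distribution with L−2 df while CIs use ±1.96·SE,
    mirroring the convention of the reference R implementation.
    """
    ins, _, _ = _arrays(instruments)
    L = len(ins)
    if L < 3:
        raise InsufficientInstrumentsError("MR-Egger needs at least 3 instruments")
    bx = np.array([i.beta_exposure for i in ins], dtype=float)
    by = np.array([i.beta_outcome for i in ins], dtype=float)
    sy = np.array([i.se_outcome for i in ins], dtype=float)
    if np.any(bx == 0):
        raise ValueError("zero exposure beta cannot be oriented for Egger regression")
    flip = bx < 0
    bx = np.where(flip, -bx, bx)
    by = np.where(flip, -by, by)

    w = 1.0 / sy**2
    X = np.column_stack([np.ones(L), bx])
    xtwx = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(xtwx, X.T @ (w * by))
    resid = by - X @ coef
    rss_w = float(np.sum(w * resid**2))
    sigma2 = rss_w / (L - 2)
    scale = max(1.0, float(np.sqrt(sigma2)))
    cov = np.linalg.inv(xtwx) * max(1.0, sigma2)
    se_int, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    q_p = float(stats.chi2.sf(rss_w, L - 2))

    def _t_p(est: float, se: float) -> float:
        return float(2 * stats.t.sf(abs(est / se), L - 2))

    slope = MREstimate(
        method="egger_slope", beta=float(coef[1]), se=se_slope,
        pvalue=_t_p(coef[1], se_slope), n_snps=L,
        q_stat=rss_w, q_pvalue=q_p, scale_factor=scale,
    )
    intercept = MREstimate(
        method="egger_intercept", beta=float(coef[0]), se=se_int,
        pvalue=_t_p(coef[0], se_int), n_snps=L,
        q_stat=rss_w, q_pvalue=q_p, scale_factor=scale,
    )
    return slope, intercept


def _weighted_median(theta: np.ndarray, weights: np.ndarray) -> float:
    # cumulative-weight interpolation: position of the j-th ordered ratio is
    # (sum of normalized weights up to j) minus half its own weight
    order = np.argsort(theta, kind="stable")
    th = theta[order]
    wn = weights[order] / weights.sum()
    pos = np.cumsum(wn) - wn / 2.0
    return float(np.interp(0.5, pos, th))


def weighted_median(
    instruments: Iterable[HarmonizedInstrument],
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Weighted-median estimate with a parametric-bootstrap standard error.

    The point estimate interpolates the ordered Wald ratios at 50% of the
    cumulative inverse-variance weight.  The SE is the standard deviation of
    the weighted median over ``n_boot`` parametric redraws
    θ_j* ~ Normal(θ_j, se(θ_j)); ``seed`` is required — there is no implicit
    global random state.
    """
    if seed is None:
        raise ValueError("weighted_median requires an explicit seed for its bootstrap")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; the bootstrap SE will be noisy", stacklevel=2)
    _, theta, se = _arrays(instruments)
    L = len(theta)
    if L < 3:
        raise InsufficientInstrumentsError("weighted median needs at least 3 instruments")
    w = 1.0 / se**2
    est = _weighted_median(theta, w)
    rng = np.random.default_rng(seed)
    draws = theta + se * rng.standard_normal((n_boot, L))
    boot = np.array([_weighted_median(d, w) for d in draws])
    se_boot = float(np.std(boot, ddof=1))
    z = est / se_boot
    return MREstimate(
        method="weighted_median",
        beta=est,
        se=se_boot,
        pvalue=float(2 * stats.norm.sf(abs(z))),
        n_snps=L,
    )


def leave_one_out(
    instruments: Iterable[HarmonizedInstrument], effects: str = "random"
) -> pd.DataFrame:
    """Random-effects IVW recomputed with each SNP excluded in turn.

    Returns a tidy table keyed by the excluded snp_id — the diagnostic for a
    single driver instrument.
    """
    ins, _, _ = _arrays(instruments)
    if len(ins) < 3:
        raise InsufficientInstrumentsError("leave-one-out needs at least 3 instruments")
    rows = []
    for j, excluded in enumerate(ins):
        subset = ins[:j] + ins[j + 1 :]
        est = ivw(subset, effects=effects) if len(subset) >= 2 else wald_ratio(subset[0])
        rows.append(
            {
                "excluded_snp": excluded.snp_id,
                "beta": est.beta,
                "se": est.se,
                "or": est.or_,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "pvalue": est.pvalue,
                "n_snps": est.n_snps,
            }
        )
    return pd.DataFrame(rows).set_index("excluded_snp")


def results_table(estimates: Sequence[MREstimate], intercept: MREstimate | None = None) -> pd.DataFrame:
    """Tidy export of a suite of estimates (one row per method)."""
    rows = []
    for est in estimates:
        rows.append(
            {
                "method": est.method,
                "n_snps": est.n_snps,
                "beta": est.beta,
                "se": est.se,
                "or": est.or_,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "pvalue": est.pvalue,
                "q": est.q_stat,
                "q_pvalue": est.q_pvalue,
                "egger_intercept": intercept.beta if (intercept and est.method == "egger_slope") else None,
                "egger_intercept_pvalue": intercept.pvalue if (intercept and est.method == "egger_slope") else None,
            }
        )
    return pd.DataFrame(rows)
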