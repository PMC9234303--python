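"""Fixed-effect meta-analysis of per-cohort MR estimates, and MR power.

Study-level causal log-ORs are pooled with inverse-variance weights (the
pooled SE can never exceed the smallest per-study SE).  Standard errors may
be back-derived from published 95% CIs via ``se_from_ci``.

The power calculation is the standard normal approximation for two-sample
MR with a binary outcome: with cohort size N, case fraction K, instrument
variance explained r², and alternative odds ratio OR,

    power = Φ( sqrt(N·r²·K·(1−K)) · |ln OR| − z_{1−α/2} ).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mr_estimators import MREstimate

__all__ = ["MetaResult", "PowerInput", "meta_fixed", "mr_power_binary", "se_from_ci", "forest_table"]

_Z95 = 1.96


def se_from_ci(ci_low: float, ci_high: float) -> float:
    """Standard error of a log-OR back-derived from a printed 95% CI."""
    if not 0 < ci_low < ci_high:
        raise ValueError("require 0 < ci_low < ci_high")
    return (np.log(ci_high) - np.log(ci_low)) / (2 * _Z95)


@dataclass(frozen=True)
class MetaResult:
    """Pooled fixed-effect estimate with between-study heterogeneity."""

    pooled_beta: float
    pooled_se: float
    pvalue: float
    q_between: float
    q_pvalue: float
    per_study: tuple[MREstimate, ...] = field(default=())

    @property
    def or_(self) -> float:
        return float(np.exp(self.pooled_beta))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.pooled_beta - _Z95 * self.pooled_se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.pooled_beta + _Z95 * self.pooled_se))


def meta_fixed(estimates: Sequence[MREstimate]) -> MetaResult:
    """Inverse-variance fixed-effect pooling of study-level estimates."""
    if len(estimates) < 2:
        raise ValueError(
            "meta-analysis needs at least 2 studies; pass a single estimate through unchanged"
        )
    beta = np.array([e.beta for e in estimates], dtype=float)
    se = np.array([e.se for e in estimates], dtype=float)
    if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(se)) and np.all(se > 0)):
        raise ValueError("all estimates must have finite beta and positive finite se")
    w = 1.0 / se**2
    pooled = float(np.sum(w * beta) / np.sum(w))
    pooled_se = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (beta - pooled) ** 2))
    q_p = float(stats.chi2.sf(q, len(estimates) - 1))
    p = float(2 * stats.norm.sf(abs(pooled / pooled_se)))
    return MetaResult(pooled, pooled_se, p, q, q_p, tuple(estimates))


def forest_table(labels: Sequence[str], estimates: Sequence[MREstimate], meta: MetaResult) -> pd.DataFrame:
    """Forest-plot data: per-study OR/CI and inverse-variance weight share."""
    w = np.array([1.0 / e.se**2 for e in estimates])
    rows = [
        {
            "study": lab,
            "or": e.or_,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
            "weight_pct": 100.0 * wi / w.sum(),
        }
        for lab, e, wi in zip(labels, estimates, w)
    ]
    rows.append(
        {"study": "pooled", "or": meta.or_, "ci_low": meta.ci_low, "ci_high": meta.ci_high, "weight_pct": 100.0}
    )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PowerInput:
    """Inputs to the binary-outcome MR power approximation."""

    n: int
    case_fraction: float
    r2: float
    or_alt: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must lie in (0, 1)")
        if not 0 < self.r2 < 1:
            raise ValueError("r2 must lie in (0, 1)")
        if self.or_alt <= 0:
            raise ValueError("or_alt must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def mr_power_binary(inp: PowerInput) -> float:
    """Approximate power of a two-sample MR test with a binary outcome."""
    ncp = np.sqrt(inp.n * inp.r2 * inp.case_fraction * (1 - inp.case_fraction)) * abs(
        np.log(inp.or_alt)
    )
    z = stats.norm.ppf(1 - inp.alpha / 2)
    return float(stats.norm.cdf(ncp - z))
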