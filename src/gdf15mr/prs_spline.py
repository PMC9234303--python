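"""Polygenic risk score and restricted-cubic-spline stage.

The individual-level complement to summary-level MR: a weighted polygenic
risk score (PRS) for GDF-15 is built from the instrument dosages, gallstone
risk is modelled by logistic regression at three covariate-adjustment levels
(Model 1: unadjusted; Model 2: age, sex, BMI, 20 genetic PCs; Model 3:
Model 2 plus deprivation, smoking, drinking, physical activity, LDL-C,
glucose, HbA1c, metformin), nonlinearity is tested with a restricted cubic
spline (Harrell basis, linear beyond the boundary knots) via a likelihood
ratio test, the turning point of a U-shaped fit is located as the argmin of
the fitted partial log-odds curve, and the population is re-analysed on each
side of that cutoff — overall and stratified by diabetic status.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "Cohort",
    "LogisticEffect",
    "SplineFit",
    "FitFailureError",
    "MODEL_COVARIATES",
    "build_prs",
    "fit_models",
    "rcs_basis",
    "default_knots",
    "fit_spline",
    "stratified_by_turning_point",
    "read_cohort",
    "write_cohort",
]

_Z95 = 1.96

_PCS = [f"pc{i}" for i in range(1, 21)]

#: Covariate sets for the three adjustment levels (nested: 1 ⊂ 2 ⊂ 3).
MODEL_COVARIATES: dict[int, list[str]] = {
    1: [],
    2: ["age", "sex", "bmi", *_PCS],
    3: [
        "age", "sex", "bmi", *_PCS,
        "deprivation", "smoking", "drinking", "physical_activity",
        "ldl", "glucose", "hba1c", "metformin",
    ],
}

_STRATA = ("all", "diabetic", "nondiabetic")


class FitFailureError(RuntimeError):
    """A logistic fit failed (separation, non-convergence, or empty stratum)."""


@dataclass
class Cohort:
    """An individual-level analysis table.

    ``dosages`` is the n×L matrix of genotype dosages (0–2 effect-allele
    copies); ``data`` holds the standardized PRS, covariates, the binary
    gallstone outcome (``gallstones``), the positive-control outcome
    (``diabetic_complications``), and the ``diabetes`` stratum flag.
    ``exposure`` optionally carries the latent exposure used to derive
    summary statistics from the same individuals.
    """

    dosages: np.ndarray
    snp_ids: list[str]
    data: pd.DataFrame
    exposure: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2 or self.dosages.shape[0] != len(self.data):
            raise ValueError("dosages must be an n×L matrix matching the data table")
        if self.dosages.shape[1] != len(self.snp_ids):
            raise ValueError("snp_ids must match the dosage column count")
        if self.dosages.size and (self.dosages.min() < 0 or self.dosages.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        for col in ("gallstones",):
            if col in self.data and not set(np.unique(self.data[col])) <= {0, 1}:
                raise ValueError(f"outcome column {col!r} must be binary 0/1")

    @property
    def n(self) -> int:
        return len(self.data)

    def subset(self, mask: np.ndarray) -> "Cohort":
        mask = np.asarray(mask, dtype=bool)
        return Cohort(
            dosages=self.dosages[mask],
            snp_ids=list(self.snp_ids),
            data=self.data.loc[mask].reset_index(drop=True),
            exposure=None if self.exposure is None else self.exposure[mask],
        )

    def stratum(self, which: str) -> "Cohort":
        if which == "all":
            return self
        if which == "diabetic":
            return self.subset(self.data["diabetes"].to_numpy() == 1)
        if which == "nondiabetic":
            return self.subset(self.data["diabetes"].to_numpy() == 0)
        raise ValueError(f"unknown stratum {which!r}; expected one of {_STRATA}")


def build_prs(dosages: np.ndarray, weights: Sequence[float], standardize: bool = True) -> np.ndarray:
    """Weighted allele score: score_i = Σⱼ βⱼ·dosage_ij.

    With ``standardize=True`` (the default — effects are reported per SD of
    genetically predicted exposure) the score is centred and scaled to unit
    sample SD.
    """
    dosages = np.asarray(dosages, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if dosages.ndim != 2 or dosages.shape[1] != weights.shape[0]:
        raise ValueError(
            f"dosage columns ({dosages.shape[1] if dosages.ndim == 2 else '?'}) "
            f"must match weight count ({weights.shape[0]})"
        )
    score = dosages @ weights
    if standardize:
        sd = score.std()
        if sd == 0:
            raise ValueError("score has zero variance; cannot standardize")
        score = (score - score.mean()) / sd
    return score


@dataclass(frozen=True)
class LogisticEffect:
    """The PRS term of a logistic fit: per-SD odds ratio with Wald CI/p."""

    beta: float
    se: float
    pvalue: float
    n: int
    n_cases: int
    model: int
    stratum: str
    outcome: str
    n_dropped: int = 0

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.beta - _Z95 * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.beta + _Z95 * self.se))


def _design(cohort: Cohort, outcome_name: str, model: int, extra: np.ndarray | None = None,
            extra_names: Sequence[str] | None = None):
    """Complete-case design matrix: const + prs (or spline columns) + covariates."""
    if model not in MODEL_COVARIATES:
        raise ValueError(f"model must be one of {sorted(MODEL_COVARIATES)}, got {model}")
    covs = MODEL_COVARIATES[model]
    missing = [c for c in covs + [outcome_name, "prs"] if c not in cohort.data.columns]
    if missing:
        raise KeyError(f"cohort is missing required column(s): {', '.join(missing)}")
    frame = cohort.data[["prs", outcome_name, *covs]].copy()
    if extra is not None:
        for k, name in enumerate(extra_names):
            frame[name] = extra[:, k]
    before = len(frame)
    frame = frame.dropna()
    n_dropped = before - len(frame)
    if n_dropped:
        logger.info("complete-case analysis dropped %d of %d rows", n_dropped, before)
    y = frame[outcome_name].to_numpy(dtype=float)
    xcols = ["prs", *(extra_names or []), *covs] if extra is None else [*(extra_names or []), *covs]
    X = sm.add_constant(frame[[c for c in xcols if c in frame.columns]], has_constant="add")
    return y, X, n_dropped


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    if y.size == 0:
        raise FitFailureError("empty analysis set")
    classes = np.unique(y)
    if classes.size < 2:
        raise FitFailureError("outcome has a single class in this stratum")
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparationError and LinAlgError
        raise FitFailureError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise FitFailureError("logistic fit did not converge")
    return res


def fit_models(
    cohort: Cohort,
    outcome_name: str = "gallstones",
    model: int = 1,
    stratum: str = "all",
) -> LogisticEffect:
    """Per-SD odds ratio of the outcome on the standardized PRS.

    Fits maximum-likelihood logistic regression of the outcome on the PRS
    plus the requested model's covariate set within the requested stratum.
    """
    sub = cohort.stratum(stratum)
    y, X, n_dropped = _design(sub, outcome_name, model)
    res = _fit_logit(y, X)
    beta = float(res.params["prs"])
    se = float(res.bse["prs"])
    return LogisticEffect(
        beta=beta,
        se=se,
        pvalue=float(2 * stats.norm.sf(abs(beta / se))),
        n=int(y.size),
        n_cases=int(y.sum()),
        model=model,
        stratum=stratum,
        outcome=outcome_name,
        n_dropped=n_dropped,
    )


def rcs_basis(x: np.ndarray, knots: Sequence[float]) -> np.ndarray:
    """Restricted cubic spline design columns (Harrell's basis).

    With k ≥ 3 strictly increasing knots t₁ < … < t_k the basis has k−1
    columns: the identity, then for j = 1..k−2

        [ (x−t_j)₊³ − (x−t_{k−1})₊³ · (t_k−t_j)/(t_k−t_{k−1})
                    + (x−t_k)₊³   · (t_{k−1}−t_j)/(t_k−t_{k−1}) ] / (t_k−t₁)²

    which is linear beyond the boundary knots and has continuous first and
    second derivatives everywhere.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    k = t.size
    if k < 3:
        raise ValueError("restricted cubic splines need at least 3 knots")
    if np.any(np.diff(t) <= 0):
        raise ValueError("knots must be strictly increasing")

    def pos3(v: np.ndarray) -> np.ndarray:
        return np.clip(v, 0.0, None) ** 3

    norm = (t[-1] - t[0]) ** 2
    cols = [x]
    for j in range(k - 2):
        term = (
            pos3(x - t[j])
            - pos3(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
            + pos3(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])
        ) / norm
        cols.append(term)
    return np.column_stack(cols)


_KNOT_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),  # Harrell's defaults
}


def default_knots(x: np.ndarray, n_knots: int = 3) -> np.ndarray:
    """Knot locations at the conventional quantiles of ``x``."""
    if n_knots not in _KNOT_QUANTILES:
        raise ValueError(f"n_knots must be one of {sorted(_KNOT_QUANTILES)}")
    return np.quantile(np.asarray(x, dtype=float), _KNOT_QUANTILES[n_knots])


@dataclass
class SplineFit:
    """A restricted-cubic-spline logistic fit of outcome on the PRS."""

    knots: np.ndarray
    coefficients: pd.Series
    nonlinearity_pvalue: float
    turning_point: float
    curve: pd.DataFrame  # columns: prs, log_odds (partial, PRS terms only)
    curve_range: float
    n: int
    n_cases: int
    model: int
    stratum: str

    @property
    def is_flat(self) -> bool:
        """True when the fitted curve spans < 0.01 log-odds — no meaningful
        turning point exists (reported anyway, but flagged)."""
        return self.curve_range < 0.01


def fit_spline(
    cohort: Cohort,
    outcome_name: str = "gallstones",
    n_knots: int = 3,
    model: int = 3,
    grid_step: float = 0.001,
    stratum: str = "all",
) -> SplineFit:
    """Nonlinearity test and turning-point location for the PRS association.

    Knots sit at conventional quantiles of the PRS.  The nonlinearity
    p-value is the likelihood-ratio test of the k−2 nonlinear spline
    coefficients jointly zero (spline model vs linear model, same
    covariates).  The turning point is the argmin of the fitted partial
    log-odds (PRS terms only) on a grid over the observed PRS range at
    resolution ``grid_step`` × SD(PRS); ties break toward the smaller PRS.
    """
    sub = cohort.stratum(stratum)
    prs = sub.data["prs"].to_numpy(dtype=float)
    knots = default_knots(prs, n_knots)
    basis = rcs_basis(prs, knots)
    names = ["prs_lin"] + [f"prs_nl{j}" for j in range(1, n_knots - 1)]

    y_full, X_full, _ = _design(sub, outcome_name, model, extra=basis, extra_names=names)
    res_full = _fit_logit(y_full, X_full)
    y_lin, X_lin, _ = _design(sub, outcome_name, model)
    res_lin = _fit_logit(y_lin, X_lin)

    lr = 2.0 * (res_full.llf - res_lin.llf)
    p_nl = float(stats.chi2.sf(max(lr, 0.0), n_knots - 2))

    sd = prs.std()
    step = grid_step * (sd if sd > 0 else 1.0)
    grid = np.arange(prs.min(), prs.max() + step / 2, step)
    spline_coef = res_full.params[names].to_numpy()
    partial = rcs_basis(grid, knots) @ spline_coef
    idx = int(np.argmin(partial))  # first minimum → smaller PRS on ties
    curve = pd.DataFrame({"prs": grid, "log_odds": partial})
    curve_range = float(partial.max() - partial.min())
    if curve_range < 0.01:
        logger.warning("spline curve range < 0.01 log-odds; turning point is not meaningful")

    return SplineFit(
        knots=knots,
        coefficients=res_full.params,
        nonlinearity_pvalue=p_nl,
        turning_point=float(grid[idx]),
        curve=curve,
        curve_range=curve_range,
        n=int(y_full.size),
        n_cases=int(y_full.sum()),
        model=model,
        stratum=stratum,
    )


def stratified_by_turning_point(
    cohort: Cohort,
    fit: SplineFit,
    model: int = 3,
    outcome_name: str = "gallstones",
) -> pd.DataFrame:
    """Linear PRS effects below and above the turning point, by stratum.

    Splits the population at ``fit.turning_point`` and refits the linear
    model on each side, for the overall, nondiabetic, and diabetic strata.
    Returns a tidy table (stratum, group, or, ci_low, ci_high, pvalue, n).
    """
    if not np.isfinite(fit.turning_point):
        raise ValueError("turning point is not finite")
    prs = cohort.data["prs"].to_numpy(dtype=float)
    rows = []
    for stratum in ("all", "nondiabetic", "diabetic"):
        for group, mask in (("low", prs < fit.turning_point), ("high", prs >= fit.turning_point)):
            side = cohort.subset(mask)
            if side.n == 0:
                raise FitFailureError(f"no individuals on the {group} side of the turning point")
            eff = fit_models(side, outcome_name=outcome_name, model=model, stratum=stratum)
            rows.append(
                {
                    "stratum": stratum,
                    "group": group,
                    "model": model,
                    "or": eff.or_,
                    "ci_low": eff.ci_low,
                    "ci_high": eff.ci_high,
                    "pvalue": eff.pvalue,
                    "n": eff.n,
                    "n_cases": eff.n_cases,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort I/O (delimited text)
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as TSV: dosage_<snp> columns followed by the data table."""
    dosage_cols = {f"dosage_{s}": cohort.dosages[:, j] for j, s in enumerate(cohort.snp_ids)}
    frame = pd.concat([pd.DataFrame(dosage_cols), cohort.data], axis=1)
    if cohort.exposure is not None:
        frame["exposure_latent"] = cohort.exposure
    frame.to_csv(path, sep="\t", index=False)


def read_cohort(path: str | Path) -> Cohort:
    """Read a cohort written by :func:`write_cohort`."""
    frame = pd.read_csv(path, sep="\t")
    dosage_cols = [c for c in frame.columns if c.startswith("dosage_")]
    if not dosage_cols:
        raise ValueError(f"{path}: no dosage_<snp> columns found")
    snp_ids = [c[len("dosage_"):] for c in dosage_cols]
    exposure = frame.pop("exposure_latent").to_numpy() if "exposure_latent" in frame else None
    dosages = frame[dosage_cols].to_numpy(dtype=float)
    data = frame.drop(columns=dosage_cols)
    return Cohort(dosages=dosages, snp_ids=snp_ids, data=data, exposure=exposure)
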