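"""Simple linear regressions of allelic statistics on distance and climate.

Each statistic is regressed on each predictor *separately* (no multiple
regression): the question is which single variable — distance from Africa or
one climate variable — best explains the worldwide pattern.  The correlation
coefficient r is reported alongside R² to carry directionality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .allele_stats import AllelicProfile

__all__ = [
    "RegressionResult",
    "DegeneratePredictorError",
    "ols",
    "wls",
    "regress_panel",
    "predictor_correlations",
    "batch_r_squared",
]

#: Column names emitted by :func:`regress_panel` for each statistic flavour.
STATISTIC_COLUMNS = {
    ("heterozygosity", False): "avg_heterozygosity",
    ("heterozygosity", True): "adj_heterozygosity",
    ("risk_frequency", False): "avg_risk_freq",
    ("risk_frequency", True): "adj_risk_freq",
}


class DegeneratePredictorError(ValueError):
    """Raised when the predictor is constant or n < 3."""


@dataclass(frozen=True)
class RegressionResult:
    response: str
    predictor: str
    slope: float
    intercept: float
    r: float
    r_squared: float
    n: int


def _validate_xy(y: np.ndarray, x: np.ndarray) -> None:
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("y and x must be aligned 1-d vectors")
    if len(x) < 3:
        raise DegeneratePredictorError("need at least 3 populations")
    if np.ptp(x) == 0:
        raise DegeneratePredictorError("constant predictor")


def ols(
    y: Sequence[float],
    x: Sequence[float],
    response: str = "y",
    predictor: str = "x",
) -> RegressionResult:
    """Ordinary least squares of y on x (closed-form simple regression)."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    _validate_xy(y, x)
    fit = scipy.stats.linregress(x, y)
    r = float(fit.rvalue)
    return RegressionResult(
        response=response,
        predictor=predictor,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=r,
        r_squared=r * r,
        n=len(x),
    )


def wls(
    y: Sequence[float],
    x: Sequence[float],
    weights: Sequence[float],
    response: str = "y",
    predictor: str = "x",
) -> RegressionResult:
    """Weighted least squares; weights are inverse variances.

    Equal weights reproduce :func:`ols` exactly.  r carries the sign of the
    slope (magnitude from the weighted R²).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    w = np.asarray(weights, dtype=float)
    _validate_xy(y, x)
    if w.shape != x.shape or (w <= 0).any() or not np.isfinite(w).all():
        raise ValueError("weights must be positive, finite and aligned")
    fit = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    slope = float(fit.params[1])
    r2 = float(fit.rsquared)
    return RegressionResult(
        response=response,
        predictor=predictor,
        slope=slope,
        intercept=float(fit.params[0]),
        r=float(np.sign(slope) * np.sqrt(max(r2, 0.0))),
        r_squared=r2,
        n=len(x),
    )


def regress_panel(
    profile: AllelicProfile,
    predictors: pd.DataFrame,
    subset: Iterable[str] | None = None,
    statistic: str = "heterozygosity",
    adjusted: bool = False,
    weights: pd.Series | None = None,
) -> list[RegressionResult]:
    """Regress one panel statistic on every predictor column.

    ``predictors`` is indexed by population (distance plus climate
    variables).  ``subset`` restricts to a population subset — e.g. the 11
    African populations, or everything but them — and must leave >= 3
    populations.  Raw statistics are the convention for distance
    regressions, adjusted statistics for climate regressions; both flavours
    are available for either via ``adjusted``.  ``weights`` (inverse
    variances, indexed by population) switches to weighted least squares.
    """
    col = STATISTIC_COLUMNS[(statistic, adjusted)]
    if col not in profile.table.columns:
        raise ValueError(f"profile lacks column {col!r}; adjust the profile first")
    pops = list(profile.table.index) if subset is None else list(subset)
    if len(pops) < 3:
        raise DegeneratePredictorError("population subset smaller than 3")
    y = profile.table.loc[pops, col].to_numpy()
    results = []
    for name in predictors.columns:
        x = predictors.loc[pops, name].to_numpy(dtype=float)
        if weights is None:
            results.append(ols(y, x, response=col, predictor=name))
        else:
            w = weights.loc[pops].to_numpy(dtype=float)
            results.append(wls(y, x, w, response=col, predictor=name))
    return results


def predictor_correlations(predictors: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations among predictor columns.

    Used to document collinearity (e.g. latitude vs. summer radiation) and
    to justify dropping a predictor above a threshold.  Constant columns
    yield NaN entries and a warning rather than a silent zero.
    """
    if predictors.shape[1] < 2:
        raise ValueError("need at least 2 predictors")
    constant = [c for c in predictors.columns if np.ptp(predictors[c].to_numpy()) == 0]
    if constant:
        warnings.warn(f"constant predictor column(s) {constant}: correlation undefined")
    return predictors.corr(method="pearson")


def batch_r_squared(Y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """R² of each row of ``Y`` (m, n) regressed on ``x`` (n,).

    Vectorised helper for resampling nulls; identical to calling
    :func:`ols` on each row.
    """
    Y = np.asarray(Y, dtype=float)
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sxx = float(xc @ xc)
    syy = np.einsum("ij,ij->i", Yc, Yc)
    sxy = Yc @ xc
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = sxy * sxy / (sxx * syy)
    # constant rows (e.g. a panel of fixed alleles) explain nothing
    return np.where(syy > 0, r2, 0.0)
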