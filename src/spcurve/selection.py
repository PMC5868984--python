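"""Fit statistics, nested tests and stepwise structure/covariance selection.

The marginal AIC counts fixed-effect columns plus free variance components;
the adjusted AIC replaces that count with the effective number of
parameters E_p = tr{ C (C'R^-1 C + B)^-1 C' R^-1 }, the trace of the
influence operator of the penalized fit, which charges each spline column
only its fractional (shrunken) degree of freedom.  Stepwise selection fits
structures 1.1-1.5 and picks the criterion minimizer; covariance selection
does the same over serial correlation families at a fixed mean structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve
from scipy.stats import chi2, f as f_dist

from .data import LongitudinalDataset
from .design import CovarianceSpec, ModelSpec, STRUCTURES, UnsupportedStructureError
from .fit import ConvergenceError, FitResult, fit as _fit

__all__ = [
    "FitStatistics",
    "SelectionReport",
    "effective_params",
    "fit_stats",
    "lrt",
    "approx_f_test",
    "stepwise_group_selection",
    "covariance_selection",
]


@dataclass
class FitStatistics:
    """-2LL, counted parameters, AIC/BIC, E_p and adjusted AIC for one fit."""

    minus2ll: float
    m: int
    aic: float
    bic: float
    e_p: float
    aic_adj: float
    n_obs: int

    @classmethod
    def from_values(cls, minus2ll: float, m: int, e_p: float, n_obs: int) -> "FitStatistics":
        return cls(
            minus2ll=minus2ll,
            m=m,
            aic=minus2ll + 2.0 * m,
            bic=minus2ll + m * np.log(n_obs),
            e_p=e_p,
            aic_adj=minus2ll + 2.0 * e_p,
            n_obs=n_obs,
        )


def effective_params(fit_result: FitResult) -> float:
    """Effective number of parameters of the penalized mean fit.

    E_p = tr{ C (C'R^-1 C + B)^-1 C'R^-1 } = tr{ (C'R^-1 C + B)^-1 A } with
    A = C'R^-1 C; equals the fixed-column count exactly when there are no
    spline columns or the spline variances vanish, and approaches
    fixed + spline column count as the smoothing variances grow.
    """
    factor = fit_result.joint_covariance_factor()
    return float(np.trace(cho_solve(factor, fit_result.A)))


def fit_stats(fit_result: FitResult) -> FitStatistics:
    """Assemble the selection-table row for one converged fit.

    ``m`` counts fixed-effect columns plus free variance components
    (subject intercept, one per spline block, serial variance and decay when
    present, white noise); BIC uses log of the total observation count.
    """
    m = fit_result.n_fixed + fit_result.n_varcomp
    return FitStatistics.from_values(
        minus2ll=fit_result.minus2ll,
        m=m,
        e_p=effective_params(fit_result),
        n_obs=fit_result.n_obs,
    )


def lrt(fit0: FitResult, fit1: FitResult) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested fixed-effect structures (ML only).

    Returns (chi-square statistic, df, p).  Refuses REML fits with differing
    fixed effects: restricted likelihoods are not comparable across mean
    structures.
    """
    if fit0.n_fixed > fit1.n_fixed:
        raise ValueError("fit0 must be the null (smaller) model")
    differs = fit0.n_fixed != fit1.n_fixed
    if differs and (fit0.method != "ML" or fit1.method != "ML"):
        raise ValueError(
            "REML fits with differing fixed effects cannot be compared by the "
            "conventional likelihood ratio test; refit with ML"
        )
    if len(fit0.varcomp.sigma2_b) != len(fit1.varcomp.sigma2_b) or (
        fit0.cov_spec.serial != fit1.cov_spec.serial
    ):
        raise ValueError("LRT requires an identical random/covariance structure")
    stat = fit0.minus2ll - fit1.minus2ll
    stat = max(float(stat), 0.0)
    df = fit1.n_fixed - fit0.n_fixed
    p = 1.0 if df == 0 and stat == 0.0 else float(chi2.sf(stat, max(df, 1)))
    if df == 0:
        p = 1.0 if stat == 0.0 else float("nan")
    return stat, df, p


def approx_f_test(fit0: FitResult, fit1: FitResult) -> tuple[float, float, float, float]:
    """Approximate F-test using residual (effective) degrees of freedom.

    F = [(RSS0 - RSS1)/(edf1 - edf0)] / [RSS1/(n - edf1)] with edf = E_p and
    RSS the covariance-weighted residual sum of squares of each fit.
    Identical models return F = 0 with p = 1.
    """
    edf0, edf1 = effective_params(fit0), effective_params(fit1)
    rss0, rss1 = fit0.rss_weighted, fit1.rss_weighted
    n = fit1.n_obs
    if edf1 - edf0 <= 1e-10:
        if abs(rss0 - rss1) <= 1e-8 * max(abs(rss1), 1.0):
            return 0.0, 0.0, float(n - edf1), 1.0
        raise ValueError("alternative model has no additional effective parameters")
    df1 = edf1 - edf0
    df2 = n - edf1
    stat = max((rss0 - rss1) / df1, 0.0) / (rss1 / df2)
    p = float(f_dist.sf(stat, df1, df2))
    return float(stat), float(df1), float(df2), p


@dataclass
class SelectionReport:
    """Per-candidate fit statistics plus the criterion minimizer."""

    table: pd.DataFrame
    chosen: str | None
    criterion: str
    fits: dict[str, FitResult]
    failures: dict[str, str]
    warnings: dict[str, list[str]]

    def to_dict(self) -> dict:
        return {
            "criterion": self.criterion,
            "chosen": self.chosen,
            "table": self.table.to_dict(orient="index"),
            "failures": dict(self.failures),
            "warnings": {k: list(v) for k, v in self.warnings.items()},
        }


_CRITERIA = {"aic": "aic", "bic": "bic", "aic_adj": "aic_adj", "minus2ll": "minus2ll"}
_STAT_ROWS = ("minus2ll", "aic", "bic", "e_p", "aic_adj")


def _select(candidates: dict[str, FitResult | str], criterion: str) -> SelectionReport:
    crit = _CRITERIA[criterion.lower()]
    rows, fits, failures, warns = {}, {}, {}, {}
    for name, obj in candidates.items():
        if isinstance(obj, str):
            failures[name] = obj
            continue
        stats = fit_stats(obj)
        rows[name] = {k: getattr(stats, k) for k in _STAT_ROWS} | {"m": stats.m}
        fits[name] = obj
        if obj.boundary_flags:
            warns[name] = [
                f"variance component {fl} at the zero boundary; fit questionable"
                for fl in obj.boundary_flags
            ]
    table = pd.DataFrame.from_dict(rows, orient="index")
    chosen = None
    if rows:
        chosen = min(rows, key=lambda k: rows[k][crit])
    return SelectionReport(
        table=table, chosen=chosen, criterion=criterion, fits=fits,
        failures=failures, warnings=warns,
    )


def stepwise_group_selection(
    dataset: LongitudinalDataset,
    model_spec: ModelSpec,
    cov_spec: CovarianceSpec | None = None,
    criterion: str = "aic_adj",
    method: str = "ML",
    structures: tuple[str, ...] = STRUCTURES,
    fit_options: dict | None = None,
) -> SelectionReport:
    """Fit the stepwise class 1.1-1.5 and select the criterion minimizer.

    ``model_spec`` supplies the basis, covariates and reference level; its
    structure field is ignored.  Structures incompatible with the data and
    fits that fail are reported per-structure and selection runs over the
    survivors.
    """
    candidates: dict[str, FitResult | str] = {}
    for s in structures:
        spec = ModelSpec(
            structure=s, basis=model_spec.basis,
            covariates=model_spec.covariates,
            reference_level=model_spec.reference_level,
        )
        try:
            candidates[s] = _fit(dataset, spec, cov_spec, method=method, options=fit_options)
        except (UnsupportedStructureError, np.linalg.LinAlgError, ValueError) as exc:
            candidates[s] = f"{type(exc).__name__}: {exc}"
        except ConvergenceError as exc:
            candidates[s] = f"ConvergenceError: {exc}"
    return _select(candidates, criterion)


def covariance_selection(
    dataset: LongitudinalDataset,
    model_spec: ModelSpec,
    serial_candidates: tuple[str, ...] = ("none", "exponential", "gaussian"),
    criterion: str = "aic_adj",
    method: str = "ML",
    fit_options: dict | None = None,
) -> SelectionReport:
    """Compare serial covariance families at a fixed mean structure."""
    candidates: dict[str, FitResult | str] = {}
    for serial in serial_candidates:
        try:
            candidates[serial] = _fit(
                dataset, model_spec, CovarianceSpec(serial=serial),
                method=method, options=fit_options,
            )
        except (np.linalg.LinAlgError, ValueError) as exc:
            candidates[serial] = f"{type(exc).__name__}: {exc}"
        except ConvergenceError as exc:
            candidates[serial] = f"ConvergenceError: {exc}"
    return _select(candidates, criterion)
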