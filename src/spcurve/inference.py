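"""Derivative and difference curves with pointwise and simultaneous bands.

All inference is conditional on the estimated variance components: the
estimation error of (beta, b) is treated as N(0, (C'R^-1 C + B)^-1), so a
contrast row c evaluated on a time grid has standard deviation
sqrt(c' (C'R^-1 C + B)^-1 c).  Pointwise bands use the normal quantile
(1.96 at 95%); simultaneous bands replace it with the simulated (1-alpha)
quantile h of the sup statistic

    max_l | (C_g e)_l / SD_l |,   e ~ N(0, (C'R^-1 C + B)^-1),

taken as the ceil((1-alpha) n_sim)-th order statistic over n_sim draws
(rank 9,500 at n_sim = 10,000).  The plug-in SD in the denominator is held
fixed across draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_solve, solve_triangular
from scipy.stats import norm

from .data import CurveTable
from .design import build_curve_design
from .fit import FitResult

__all__ = [
    "BandResult",
    "derivative_curve",
    "difference_curve",
    "pointwise_band",
    "simultaneous_band",
    "simultaneous_band_derivative",
]


@dataclass
class BandResult:
    """A curve estimate with symmetric confidence bands on a grid."""

    grid: np.ndarray
    estimate: np.ndarray
    sd: np.ndarray
    multiplier: float
    level: float
    kind: str  # "pointwise" or "simultaneous"
    n_sim: int | None = None
    seed: int | None = None
    label: str = ""

    @property
    def lower(self) -> np.ndarray:
        return self.estimate - self.multiplier * self.sd

    @property
    def upper(self) -> np.ndarray:
        return self.estimate + self.multiplier * self.sd

    def covers(self, truth: np.ndarray) -> bool:
        """True when ``truth`` lies inside the band at every grid point."""
        truth = np.asarray(truth, float)
        return bool(np.all((self.lower <= truth) & (truth <= self.upper)))

    def covers_pointwise(self, truth: np.ndarray) -> np.ndarray:
        truth = np.asarray(truth, float)
        return (self.lower <= truth) & (truth <= self.upper)

    def to_curve_table(self) -> CurveTable:
        return CurveTable(
            grid=self.grid, label=self.label, estimate=self.estimate,
            sd=self.sd, lower=self.lower, upper=self.upper,
        )


def _contrast_rows(
    fit: FitResult, grid: np.ndarray, group_l: str, group_lp: str, derivative: bool
) -> np.ndarray:
    """C_g rows for f_l - f_l' (covariate columns cancel at equal values)."""
    Xl, Zl = build_curve_design(fit.design, grid, group_l, derivative=derivative)
    Xp, Zp = build_curve_design(fit.design, grid, group_lp, derivative=derivative)
    return np.hstack([Xl - Xp, Zl - Zp])


def _single_rows(fit: FitResult, grid: np.ndarray, group: str, derivative: bool) -> np.ndarray:
    Xg, Zg = build_curve_design(fit.design, grid, group, derivative=derivative)
    return np.hstack([Xg, Zg])


def _sd_from_precision(fit: FitResult, Cg: np.ndarray) -> np.ndarray:
    factor = fit.joint_covariance_factor()
    half = cho_solve(factor, Cg.T)  # (q, T): P^-1 Cg'
    return np.sqrt(np.einsum("ij,ji->i", Cg, half))


def derivative_curve(
    fit: FitResult, grid: np.ndarray, group: str
) -> CurveTable:
    """Plug-in rate-of-change estimate f'_l(g) from the fitted coefficients."""
    grid = np.asarray(grid, float).ravel()
    Cg = _single_rows(fit, grid, group, derivative=True)
    est = Cg @ fit.coef
    sd = _sd_from_precision(fit, Cg)
    return CurveTable(grid=grid, label=f"d/dt {group}", estimate=est, sd=sd)


def difference_curve(
    fit: FitResult, grid: np.ndarray, group_l: str, group_lp: str
) -> CurveTable:
    """Estimated between-group difference f_l - f_l' and its pointwise SD."""
    if group_l == group_lp:
        raise ValueError("difference requires two distinct groups")
    grid = np.asarray(grid, float).ravel()
    Cg = _contrast_rows(fit, grid, group_l, group_lp, derivative=False)
    est = Cg @ fit.coef
    sd = _sd_from_precision(fit, Cg)
    return CurveTable(grid=grid, label=f"{group_l}-{group_lp}", estimate=est, sd=sd)


def pointwise_band(
    fit: FitResult, grid: np.ndarray, group_l: str, group_lp: str, level: float = 0.95
) -> BandResult:
    """Normal-quantile pointwise band for the between-group difference."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    curve = difference_curve(fit, grid, group_l, group_lp)
    z = float(norm.ppf(0.5 + level / 2.0))
    return BandResult(
        grid=curve.grid, estimate=curve.estimate, sd=curve.sd, multiplier=z,
        level=level, kind="pointwise", label=curve.label,
    )


def sup_quantile_index(level: float, n_sim: int) -> int:
    """1-based order-statistic rank for h_{level}: ceil(level * n_sim)."""
    return int(np.ceil(level * n_sim))


def _simulated_multiplier(
    fit: FitResult, Cg: np.ndarray, sd: np.ndarray, level: float, n_sim: int, seed: int
) -> float:
    factor = fit.joint_covariance_factor()
    L = np.tril(factor[0]) if factor[1] else np.triu(factor[0]).T
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((L.shape[0], n_sim))
    draws = solve_triangular(L.T, z, lower=False)  # columns ~ N(0, P^-1)
    # grid points with exactly zero SD (degenerate contrasts) impose no
    # constraint on the sup statistic
    safe_sd = np.where(sd > 0, sd, np.inf)
    sup = np.max(np.abs((Cg @ draws) / safe_sd[:, None]), axis=0)
    rank = sup_quantile_index(level, n_sim)
    return float(np.sort(sup)[rank - 1])


def simultaneous_band(
    fit: FitResult,
    grid: np.ndarray,
    group_l: str,
    group_lp: str,
    level: float = 0.95,
    n_sim: int = 10000,
    seed: int = 0,
) -> BandResult:
    """Simulation-based simultaneous band for the between-group difference."""
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    curve = difference_curve(fit, grid, group_l, group_lp)
    Cg = _contrast_rows(fit, curve.grid, group_l, group_lp, derivative=False)
    h = _simulated_multiplier(fit, Cg, curve.sd, level, n_sim, seed)
    return BandResult(
        grid=curve.grid, estimate=curve.estimate, sd=curve.sd, multiplier=h,
        level=level, kind="simultaneous", n_sim=n_sim, seed=seed, label=curve.label,
    )


def simultaneous_band_derivative(
    fit: FitResult,
    grid: np.ndarray,
    group: str | None = None,
    contrast: tuple[str, str] | None = None,
    level: float = 0.95,
    n_sim: int = 10000,
    seed: int = 0,
) -> BandResult:
    """Simultaneous band for a derivative curve or derivative contrast.

    Exactly one of ``group`` (single-group f') or ``contrast``
    (f'_l - f'_l') must be given.
    """
    if (group is None) == (contrast is None):
        raise ValueError("give exactly one of 'group' or 'contrast'")
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    grid = np.asarray(grid, float).ravel()
    if group is not None:
        Cg = _single_rows(fit, grid, group, derivative=True)
        label = f"d/dt {group}"
    else:
        l, lp = contrast
        if l == lp:
            raise ValueError("contrast requires two distinct groups")
        Cg = _contrast_rows(fit, grid, l, lp, derivative=True)
        label = f"d/dt ({l}-{lp})"
    est = Cg @ fit.coef
    sd = _sd_from_precision(fit, Cg)
    h = _simulated_multiplier(fit, Cg, sd, level, n_sim, seed)
    return BandResult(
        grid=grid, estimate=est, sd=sd, multiplier=h, level=level,
        kind="simultaneous", n_sim=n_sim, seed=seed, label=label,
    )
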