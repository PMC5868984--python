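"""Design-matrix assembly for the stepwise model class and covariance algebra.

The five mean-response structures form a stepwise class for testing
group-by-curve interactions on top of a shared quadratic P-spline backbone:

* ``1.1`` (common): one smooth curve for all groups.
* ``1.2`` (parallel): adds a group intercept — a constant vertical shift.
* ``1.3`` (quadratic-by-group): group-specific intercept, slope and
  curvature; groups share one set of spline coefficients.
* ``1.4`` (split splines): fixed part as 1.3 plus separate spline
  coefficient vectors per group (indicator-masked blocks) sharing one
  smoothing variance.
* ``1.5`` (split splines, split variance): as 1.4 with a distinct spline
  variance per group block.

Serial within-subject correlation follows a stationary Gaussian process with
exponential, exp(-|dt|/tau), or Gaussian, exp(-(dt/tau)^2), correlation, on
top of a white-noise floor and a subject random intercept.  The marginal
covariance V = Z_b D Z_b' + blockdiag_i(sigma_u^2 J + Sigma_i) is never
materialized densely: :class:`MarginalCovariance` works through per-subject
blocks and a low-rank (Woodbury) update over the spline columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .basis import BasisSpec, truncated_power_basis, truncated_power_derivative
from .data import LongitudinalDataset

__all__ = [
    "STRUCTURES",
    "ModelSpec",
    "DesignMatrices",
    "CovarianceSpec",
    "VarianceComponents",
    "UnsupportedStructureError",
    "build_design",
    "build_curve_design",
    "serial_covariance",
    "MarginalCovariance",
]

STRUCTURES = ("1.1", "1.2", "1.3", "1.4", "1.5")
_ALIASES = {
    "common": "1.1",
    "parallel": "1.2",
    "quadratic_by_group": "1.3",
    "split_splines": "1.4",
    "split_splines_split_variance": "1.5",
}


class UnsupportedStructureError(ValueError):
    """Structure incompatible with the data (e.g. split splines with L != 2)."""


@dataclass(frozen=True)
class ModelSpec:
    """Mean-structure choice: stepwise structure, basis and covariates."""

    structure: str = "1.1"
    basis: BasisSpec = field(default_factory=BasisSpec)
    covariates: tuple[str, ...] = ()
    reference_level: str | None = None

    def __post_init__(self) -> None:
        s = _ALIASES.get(self.structure, self.structure)
        if s not in STRUCTURES:
            raise UnsupportedStructureError(f"unknown structure {self.structure!r}")
        object.__setattr__(self, "structure", s)


@dataclass(frozen=True)
class CovarianceSpec:
    """Within-subject covariance structure (serial process + white noise).

    ``serial`` selects the correlation family; the variance/decay fields are
    generating or starting values — the fitter estimates its own.
    """

    serial: str = "none"
    sigma2_u: float = 0.0
    sigma2_serial: float = 0.0
    tau: float = 1.0
    sigma2_noise: float = 1.0

    def __post_init__(self) -> None:
        if self.serial not in ("none", "exponential", "gaussian"):
            raise ValueError(f"unknown serial structure {self.serial!r}")
        if self.serial != "none" and self.tau <= 0:
            raise ValueError("tau must be positive for a serial process")
        for name in ("sigma2_u", "sigma2_serial", "sigma2_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class VarianceComponents:
    """Estimated (or generating) variance components on the natural scale.

    ``sigma2_b`` holds one spline variance per spline block (one entry for
    structures 1.1-1.4, two for 1.5).
    """

    sigma2_u: float
    sigma2_b: tuple[float, ...]
    sigma2_noise: float
    sigma2_serial: float = 0.0
    tau: float = 1.0
    serial: str = "none"

    def as_dict(self) -> dict:
        out = {
            "sigma2_u": self.sigma2_u,
            "sigma2_b": list(self.sigma2_b),
            "sigma2_noise": self.sigma2_noise,
            "serial": self.serial,
        }
        if self.serial != "none":
            out["sigma2_serial"] = self.sigma2_serial
            out["tau"] = self.tau
        return out


@dataclass
class DesignMatrices:
    """X (fixed), Z_b (spline random), subject structure and column labels."""

    X: np.ndarray
    Zb: np.ndarray
    x_names: tuple[str, ...]
    spline_block_map: tuple[tuple[int, ...], ...]
    subject_slices: dict[str, slice]
    times: np.ndarray
    model_spec: ModelSpec
    group_levels: tuple[str, ...]

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_fixed(self) -> int:
        return self.X.shape[1]

    @property
    def n_spline(self) -> int:
        return self.Zb.shape[1]

    def C(self) -> np.ndarray:
        """Joint mean design C = [X Z_b]."""
        return np.hstack([self.X, self.Zb])


def _ordered_levels(dataset: LongitudinalDataset, spec: ModelSpec) -> tuple[str, ...]:
    levels = list(dataset.group_levels)
    if spec.reference_level is not None:
        if spec.reference_level not in levels:
            raise ValueError(f"reference level {spec.reference_level!r} not a group label")
        levels.remove(spec.reference_level)
        levels.insert(0, spec.reference_level)
    return tuple(levels)


def build_design(dataset: LongitudinalDataset, spec: ModelSpec) -> DesignMatrices:
    """Assemble X, Z_b and the spline variance block map for one structure.

    Column order follows the stepwise parameterization: intercept, group
    indicators, t, group x t, t^2, group x t^2, ..., then covariates.  The
    first group level (or ``spec.reference_level``) is coded 0.
    """
    levels = _ordered_levels(dataset, spec)
    structure = spec.structure
    if structure in ("1.4", "1.5") and len(levels) != 2:
        raise UnsupportedStructureError(
            f"structure {structure} requires exactly two groups, got {len(levels)}"
        )
    missing = [c for c in spec.covariates if c not in dataset.covariates]
    if missing:
        raise ValueError(f"covariates not present in dataset: {missing}")

    t = dataset.times()
    basis = truncated_power_basis(t, spec.basis)
    p = spec.basis.n_poly
    poly, trunc = basis[:, :p], basis[:, p:]

    group_per_obs = dataset.frame["group"].to_numpy()
    indicators = np.column_stack(
        [(group_per_obs == lev).astype(float) for lev in levels[1:]]
    ) if len(levels) > 1 else np.empty((len(t), 0))

    cols: list[np.ndarray] = [np.ones(len(t))]
    names: list[str] = ["intercept"]
    if structure in ("1.2", "1.3", "1.4", "1.5"):
        for j, lev in enumerate(levels[1:]):
            cols.append(indicators[:, j])
            names.append(f"group[{lev}]")
    for d in range(p):
        cols.append(poly[:, d])
        names.append(f"t^{d + 1}")
        if structure in ("1.3", "1.4", "1.5"):
            for j, lev in enumerate(levels[1:]):
                cols.append(indicators[:, j] * poly[:, d])
                names.append(f"group[{lev}]:t^{d + 1}")
    for c in spec.covariates:
        cols.append(dataset.frame[c].to_numpy(float))
        names.append(c)
    X = np.column_stack(cols)

    K = spec.basis.n_spline
    if structure in ("1.1", "1.2", "1.3"):
        Zb = trunc
        block_map: tuple[tuple[int, ...], ...] = (tuple(range(K)),) if K else ()
    else:
        ref_mask = (group_per_obs == levels[0]).astype(float)[:, None]
        ind_mask = (group_per_obs == levels[1]).astype(float)[:, None]
        Zb = np.hstack([ind_mask * trunc, ref_mask * trunc])
        if structure == "1.4":
            block_map = (tuple(range(2 * K)),) if K else ()
        else:
            block_map = (tuple(range(K)), tuple(range(K, 2 * K))) if K else ()

    slices: dict[str, slice] = {}
    subj = dataset.frame["subject"].to_numpy()
    start = 0
    for s in dataset.subjects:
        n_i = int((subj == s).sum())
        slices[s] = slice(start, start + n_i)
        start += n_i

    return DesignMatrices(
        X=X,
        Zb=Zb,
        x_names=tuple(names),
        spline_block_map=block_map,
        subject_slices=slices,
        times=t,
        model_spec=spec,
        group_levels=levels,
    )


def build_curve_design(
    design: DesignMatrices,
    grid: np.ndarray,
    group: str,
    covariate_values: dict[str, float] | None = None,
    derivative: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Rows of (X, Z_b) evaluating the group-``group`` curve on ``grid``.

    Covariates default to zero (the curve is then the mean response at
    covariate values equal to zero).  With ``derivative=True`` the rows
    evaluate f'(g) instead of f(g); intercept-like columns drop to zero.
    """
    spec = design.model_spec
    levels = design.group_levels
    if group not in levels:
        raise ValueError(f"unknown group {group!r}; levels are {levels}")
    grid = np.asarray(grid, float).ravel()
    p = spec.basis.n_poly
    if derivative:
        b = truncated_power_derivative(grid, spec.basis)
    else:
        b = truncated_power_basis(grid, spec.basis)
    poly, trunc = b[:, :p], b[:, p:]
    ind = {lev: float(lev == group) for lev in levels[1:]}

    cols: list[np.ndarray] = [np.full(grid.size, 0.0 if derivative else 1.0)]
    structure = spec.structure
    if structure in ("1.2", "1.3", "1.4", "1.5"):
        for lev in levels[1:]:
            cols.append(np.full(grid.size, 0.0 if derivative else ind[lev]))
    for d in range(p):
        cols.append(poly[:, d])
        if structure in ("1.3", "1.4", "1.5"):
            for lev in levels[1:]:
                cols.append(ind[lev] * poly[:, d])
    cov_vals = covariate_values or {}
    for c in spec.covariates:
        val = 0.0 if derivative else float(cov_vals.get(c, 0.0))
        cols.append(np.full(grid.size, val))
    Xg = np.column_stack(cols)

    if structure in ("1.1", "1.2", "1.3"):
        Zg = trunc
    else:
        Zg = np.hstack([ind[levels[1]] * trunc, (1.0 - ind[levels[1]]) * trunc])
    return Xg, Zg


def serial_covariance(times: np.ndarray, spec: CovarianceSpec) -> np.ndarray:
    """Per-subject within-subject covariance Sigma_i = serial + white noise.

    Diagonal is sigma2_serial + sigma2_noise; off-diagonals decay with the
    chosen correlation family.  The subject random intercept is *not*
    included here (see :class:`MarginalCovariance`).
    """
    t = np.asarray(times, float).ravel()
    if not np.isfinite(t).all():
        raise ValueError("times must be finite")
    n = t.size
    out = spec.sigma2_noise * np.eye(n)
    if spec.serial != "none" and spec.sigma2_serial > 0:
        lag = np.abs(t[:, None] - t[None, :])
        if spec.serial == "exponential":
            corr = np.exp(-lag / spec.tau)
        else:
            corr = np.exp(-((lag / spec.tau) ** 2))
        out += spec.sigma2_serial * corr
    elif spec.serial != "none":
        pass  # sigma2_serial == 0 degenerates to white noise only
    return out


def _serial_corr(lag: np.ndarray, serial: str, tau: float) -> np.ndarray:
    if serial == "exponential":
        return np.exp(-lag / tau)
    if serial == "gaussian":
        return np.exp(-((lag / tau) ** 2))
    raise ValueError(serial)


class _PatternGroup:
    """Subjects sharing an identical time vector, stacked for batched algebra."""

    __slots__ = ("times", "lag", "T", "count")

    def __init__(self, times: np.ndarray, blocks: list[np.ndarray]):
        self.times = times
        self.lag = np.abs(times[:, None] - times[None, :])
        self.T = np.stack(blocks)  # (m, n_t, q) stacked [C_i y_i] blocks
        self.count = len(blocks)


class MarginalCovariance:
    """Low-rank + block-diagonal marginal covariance of the response.

    V = Z_b D Z_b' + R with R = blockdiag_i(sigma_u^2 J + Sigma_i); D is
    diagonal with one variance per spline block.  Provides solves against V
    and R, the log-determinant, and the whitened cross-products the profiled
    likelihood needs, all without forming the dense N x N matrix.  Subjects
    with identical time vectors share one Cholesky factorization.
    """

    def __init__(self, design: DesignMatrices, serial: str = "none"):
        self.design = design
        self.serial = serial
        self._groups: list[_PatternGroup] = []
        self._order: list[np.ndarray] = []  # row indices per group, stacked
        C = design.C()
        by_pattern: dict[tuple, tuple[np.ndarray, list, list]] = {}
        for s, sl in design.subject_slices.items():
            t_i = design.times[sl]
            key = tuple(np.round(t_i, 10))
            if key not in by_pattern:
                by_pattern[key] = (t_i, [], [])
            by_pattern[key][1].append(C[sl])
            by_pattern[key][2].append(np.arange(sl.start, sl.stop))
        for t_i, blocks, rows in by_pattern.values():
            self._groups.append(_PatternGroup(t_i, blocks))
            self._order.append(np.asarray(rows))
        self.n_obs = design.n_obs
        self.q = C.shape[1]
        self.n_fixed = design.n_fixed
        self._fast_cache: tuple | None = None

    def _fast_precompute(self, y: np.ndarray):
        """Gram-matrix sufficient statistics for the serial-free residual.

        With R_i = sigma_u^2 J + sigma_w^2 I, Sherman-Morrison gives
        C_i'R_i^-1 C_i = (G_i - c_i s_i s_i') / sigma_w^2 with
        c_i = sigma_u^2 / (sigma_w^2 + n_i sigma_u^2) and s_i = C_i'1, so a
        likelihood evaluation reduces to scalar reweighting of precomputed
        Grams.
        """
        if self._fast_cache is not None and np.array_equal(self._fast_cache[0], y):
            return self._fast_cache[1:]
        Gtot = np.zeros((self.q + 1, self.q + 1))
        per_pattern = []
        for g, rows in zip(self._groups, self._order):
            Ty = np.concatenate([g.T, y[rows][:, :, None]], axis=2)
            Gtot += np.einsum("mij,mik->jk", Ty, Ty)
            S = Ty.sum(axis=1)  # (m, q+1) per-subject column sums
            per_pattern.append((g.times.size, g.count, S.T @ S))
        self._fast_cache = (np.asarray(y, float).copy(), Gtot, per_pattern)
        return Gtot, per_pattern

    # -- R-level algebra --------------------------------------------------
    def _R_block(self, vc: VarianceComponents, g: _PatternGroup) -> np.ndarray:
        n = g.times.size
        R = vc.sigma2_noise * np.eye(n) + vc.sigma2_u * np.ones((n, n))
        if vc.serial != "none" and vc.sigma2_serial > 0:
            R += vc.sigma2_serial * _serial_corr(g.lag, vc.serial, vc.tau)
        return R

    def whitened_products(self, vc: VarianceComponents, y: np.ndarray):
        """Accumulate A = C'R^-1 C, b = C'R^-1 y, s = y'R^-1 y, log|R|."""
        q = self.q
        if vc.serial == "none":
            Gtot, per_pattern = self._fast_precompute(y)
            s2u, s2w = vc.sigma2_u, vc.sigma2_noise
            A = Gtot.copy()
            logdetR = 0.0
            for n_i, count, P in per_pattern:
                A -= (s2u / (s2w + n_i * s2u)) * P
                logdetR += count * ((n_i - 1) * np.log(s2w) + np.log(s2w + n_i * s2u))
            A /= s2w
            return A[:q, :q], A[:q, q], float(A[q, q]), logdetR
        A = np.zeros((q + 1, q + 1))
        logdetR = 0.0
        for g, rows in zip(self._groups, self._order):
            R = self._R_block(vc, g)
            try:
                L = np.linalg.cholesky(R)
            except np.linalg.LinAlgError as exc:
                raise np.linalg.LinAlgError(
                    f"residual covariance block not positive definite: {vc}"
                ) from exc
            logdetR += 2.0 * g.count * np.log(np.diag(L)).sum()
            Ty = np.concatenate([g.T, y[rows][:, :, None]], axis=2)
            Linv = solve_triangular(L, np.eye(L.shape[0]), lower=True)
            W = Linv @ Ty
            A += np.einsum("mij,mik->jk", W, W)
        return A[:q, :q], A[:q, q], float(A[q, q]), logdetR

    def solve_R(self, vec_or_mat: np.ndarray, vc: VarianceComponents) -> np.ndarray:
        """R^{-1} v applied block-by-block (v may have trailing columns)."""
        v = np.asarray(vec_or_mat, float)
        out = np.empty_like(v)
        for g, rows in zip(self._groups, self._order):
            R = self._R_block(vc, g)
            cf = cho_factor(R, lower=True)
            for r in rows:
                out[r] = cho_solve(cf, v[r])
        return out

    # -- V-level algebra (Woodbury over the spline columns) ---------------
    def _spline_variance_diag(self, vc: VarianceComponents) -> np.ndarray:
        d = np.empty(self.design.n_spline)
        for var, cols in zip(vc.sigma2_b, self.design.spline_block_map):
            d[list(cols)] = var
        return d

    def solve_V(self, vec: np.ndarray, vc: VarianceComponents) -> np.ndarray:
        """V^{-1} v with V = Z_b D Z_b' + R via the Woodbury identity."""
        Zb = self.design.Zb
        d = self._spline_variance_diag(vc)
        Rin_v = self.solve_R(vec, vc)
        if Zb.shape[1] == 0 or np.all(d == 0):
            return Rin_v
        Rin_Z = self.solve_R(Zb, vc)
        M = np.diag(1.0 / d) + Zb.T @ Rin_Z
        return Rin_v - Rin_Z @ np.linalg.solve(M, Zb.T @ Rin_v)

    def logdet_V(self, vc: VarianceComponents) -> float:
        Zb = self.design.Zb
        d = self._spline_variance_diag(vc)
        logdetR = 0.0
        for g in self._groups:
            R = self._R_block(vc, g)
            L = np.linalg.cholesky(R)
            logdetR += 2.0 * g.count * np.log(np.diag(L)).sum()
        if Zb.shape[1] == 0 or np.all(d == 0):
            return logdetR
        Rin_Z = self.solve_R(Zb, vc)
        M = np.diag(1.0 / d) + Zb.T @ Rin_Z
        sign, ldM = np.linalg.slogdet(M)
        if sign <= 0:
            raise np.linalg.LinAlgError("Woodbury core not positive definite")
        return logdetR + np.log(d).sum() + ldM
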