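"""ML/REML estimation for the P-spline linear mixed model.

The marginal model is Y ~ N(X beta, V) with
V = Z_b D Z_b' + blockdiag_i(sigma_u^2 J + Sigma_i): spline coefficients act
as Gaussian random effects (one variance per spline block, which is the
smoothing parameter), subjects contribute random intercepts, and Sigma_i is
the serial-plus-white-noise within-subject covariance.  Variance components
are optimized on the log scale with beta profiled out by generalized least
squares at every iterate; (beta, b) then solve the penalized normal
equations (C'R^-1 C + B) theta = C'R^-1 y with C = [X Z_b] and
B = blockdiag(0, D^-1), whose inverse is the conditional joint covariance of
the estimation error used for all downstream inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .data import CurveTable, LongitudinalDataset
from .design import (
    CovarianceSpec,
    DesignMatrices,
    MarginalCovariance,
    ModelSpec,
    VarianceComponents,
    build_curve_design,
    build_design,
)

__all__ = ["FitResult", "ConvergenceError", "fit", "eblup_coefficients", "predict_curve"]

BOUNDARY_TOL = 1e-8
_LOG_CLIP = 40.0


class ConvergenceError(RuntimeError):
    """Optimizer failed to converge; carries the best point found."""

    def __init__(self, msg: str, best: "FitResult | None" = None):
        super().__init__(msg)
        self.best = best


@dataclass
class FitResult:
    """Converged model fit: estimates, EBLUPs, likelihood and precision."""

    method: str
    model_spec: ModelSpec
    cov_spec: CovarianceSpec
    design: DesignMatrices
    varcomp: VarianceComponents
    beta: np.ndarray
    b: np.ndarray
    u: dict[str, float]
    minus2ll: float
    converged: bool
    n_iter: int
    boundary_flags: tuple[str, ...]
    y: np.ndarray
    # penalized normal-equation pieces (C'R^-1 C, C'R^-1 y, penalty diag)
    A: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    bvec: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    penalty_diag: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    rss_weighted: float = float("nan")
    engine: MarginalCovariance = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def n_obs(self) -> int:
        return self.design.n_obs

    @property
    def n_fixed(self) -> int:
        return self.design.n_fixed

    @property
    def coef(self) -> np.ndarray:
        """Joint (beta, b) coefficient vector."""
        return np.concatenate([self.beta, self.b])

    @property
    def n_varcomp(self) -> int:
        n = 2 + len(self.varcomp.sigma2_b)  # sigma_u^2, sigma_w^2, spline blocks
        if self.varcomp.serial != "none":
            n += 2  # sigma_delta^2, tau
        return n

    def joint_precision(self) -> np.ndarray:
        """C'R^-1 C + B: the precision of the (beta, b) estimation error."""
        P = self.A.copy()
        p = self.n_fixed
        idx = np.arange(p, P.shape[0])
        P[idx, idx] += self.penalty_diag
        return P

    def joint_covariance_factor(self):
        """Cholesky factorization of the joint precision (for solves/draws)."""
        return cho_factor(self.joint_precision(), lower=True)

    def summary(self) -> dict:
        return {
            "method": self.method,
            "structure": self.model_spec.structure,
            "serial": self.cov_spec.serial,
            "minus2ll": self.minus2ll,
            "n_obs": self.n_obs,
            "n_fixed": self.n_fixed,
            "beta": {n: float(v) for n, v in zip(self.design.x_names, self.beta)},
            "varcomp": self.varcomp.as_dict(),
            "converged": self.converged,
            "n_iter": self.n_iter,
            "boundary_flags": list(self.boundary_flags),
        }


def _param_layout(design: DesignMatrices, cov_spec: CovarianceSpec) -> list[str]:
    names = ["sigma2_u"]
    names += [f"sigma2_b[{i}]" for i in range(len(design.spline_block_map))]
    if cov_spec.serial != "none":
        names += ["sigma2_serial", "tau"]
    names.append("sigma2_noise")
    return names


def _unpack(x: np.ndarray, design: DesignMatrices, serial: str) -> VarianceComponents:
    vals = np.exp(np.clip(x, -_LOG_CLIP, _LOG_CLIP))
    n_blocks = len(design.spline_block_map)
    i = 0
    s2u = vals[i]; i += 1
    s2b = tuple(vals[i : i + n_blocks]); i += n_blocks
    if serial != "none":
        s2d, tau = vals[i], vals[i + 1]; i += 2
    else:
        s2d, tau = 0.0, 1.0
    s2w = vals[i]
    return VarianceComponents(
        sigma2_u=s2u, sigma2_b=s2b, sigma2_noise=s2w,
        sigma2_serial=s2d, tau=tau, serial=serial,
    )


def _profiled_neg2ll(vc, engine, y, p, method):
    """-2 log-likelihood with beta profiled out via GLS (ML or REML)."""
    A, bvec, s, logdetR = engine.whitened_products(vc, y)
    d = engine._spline_variance_diag(vc)
    Axx, Axs, Ass = A[:p, :p], A[:p, p:], A[p:, p:]
    bx, bs = bvec[:p], bvec[p:]
    if d.size:
        M = Ass + np.diag(1.0 / d)
        cfM = cho_factor(M, lower=True)
        Minv_Asx = cho_solve(cfM, Axs.T)
        Minv_bs = cho_solve(cfM, bs)
        XtWX = Axx - Axs @ Minv_Asx
        XtWy = bx - Axs @ Minv_bs
        yWy = s - bs @ Minv_bs
        ldM = 2.0 * np.log(np.diag(cfM[0])).sum()
        logdetV = logdetR + np.log(d).sum() + ldM
    else:
        XtWX, XtWy, yWy = Axx, bx, s
        logdetV = logdetR
    cfX = cho_factor(XtWX, lower=True)
    beta = cho_solve(cfX, XtWy)
    quad = yWy - XtWy @ beta
    n = engine.n_obs
    if method == "ML":
        val = n * np.log(2 * np.pi) + logdetV + quad
    else:
        ldX = 2.0 * np.log(np.diag(cfX[0])).sum()
        val = (n - p) * np.log(2 * np.pi) + logdetV + ldX + quad
    return val, beta, (A, bvec, s, d)


def _start_values(design: DesignMatrices, cov_spec: CovarianceSpec, y: np.ndarray) -> np.ndarray:
    """Moment-based starting point on the log scale."""
    C = design.C()
    coef, *_ = np.linalg.lstsq(C, y, rcond=None)
    resid = y - C @ coef
    subj_means = [resid[sl].mean() for sl in design.subject_slices.values()]
    s2u = max(float(np.var(subj_means)), 1e-6)
    within = np.concatenate(
        [resid[sl] - resid[sl].mean() for sl in design.subject_slices.values()]
    )
    s2w = max(float(np.var(within)), 1e-6)
    n_spline = design.n_spline
    b_ols = coef[design.n_fixed :]
    s2b = max(float(np.mean(b_ols**2)) if n_spline else 1e-4, 1e-10)
    x = [np.log(s2u)] + [np.log(s2b)] * len(design.spline_block_map)
    if cov_spec.serial != "none":
        t = design.times
        tau0 = max((t.max() - t.min()) / 10.0, 1e-3)
        x += [np.log(max(s2w / 2.0, 1e-8)), np.log(tau0)]
        x += [np.log(max(s2w / 2.0, 1e-8))]
    else:
        x += [np.log(s2w)]
    return np.asarray(x)


def fit(
    dataset: LongitudinalDataset,
    model_spec: ModelSpec,
    cov_spec: CovarianceSpec | None = None,
    method: str = "ML",
    options: dict | None = None,
) -> FitResult:
    """Fit one stepwise structure by ML (default) or REML.

    Variance components are optimized on the log scale with Nelder-Mead
    (restarted once from the optimum to polish); the fit is deterministic
    given data, spec and options.  A ``ConvergenceError`` carries the
    best-so-far result; near-zero variance estimates set boundary flags
    rather than failing.
    """
    if method not in ("ML", "REML"):
        raise ValueError("method must be 'ML' or 'REML'")
    cov_spec = cov_spec or CovarianceSpec()
    opts = {"maxiter": 4000, "fatol": 1e-9, "xatol": 1e-7, "n_restarts": 1}
    if options:
        opts.update(options)

    design = build_design(dataset, model_spec)
    y = dataset.response()
    p = design.n_fixed
    if design.n_obs <= p + len(_param_layout(design, cov_spec)):
        raise ValueError("fewer observations than counted parameters")
    engine = MarginalCovariance(design, serial=cov_spec.serial)

    def objective(x: np.ndarray) -> float:
        vc = _unpack(x, design, cov_spec.serial)
        try:
            val, _, _ = _profiled_neg2ll(vc, engine, y, p, method)
        except np.linalg.LinAlgError:
            return 1e12
        return val if np.isfinite(val) else 1e12

    x0 = _start_values(design, cov_spec, y)
    if cov_spec.serial != "none" and cov_spec.tau > 0 and cov_spec.sigma2_serial > 0:
        # caller-supplied starting values for the serial process
        names = _param_layout(design, cov_spec)
        x0[names.index("sigma2_serial")] = np.log(cov_spec.sigma2_serial)
        x0[names.index("tau")] = np.log(cov_spec.tau)

    best = None
    n_iter_total = 0
    x_cur = x0
    for _ in range(1 + int(opts["n_restarts"])):
        res = minimize(
            objective, x_cur, method="Nelder-Mead",
            options={"maxiter": opts["maxiter"], "fatol": opts["fatol"],
                     "xatol": opts["xatol"], "adaptive": True},
        )
        n_iter_total += res.nit
        if best is None or res.fun < best.fun:
            best = res
        x_cur = best.x
    converged = bool(best.fun < 1e11)

    vc = _unpack(best.x, design, cov_spec.serial)
    minus2ll, beta, (A, bvec, s, d) = _profiled_neg2ll(vc, engine, y, p, method)

    # penalized normal equations for the joint (beta, b) solution
    q = A.shape[0]
    pen = np.zeros(q - p) if q > p else np.zeros(0)
    if d.size:
        pen = 1.0 / d
    A_pen = A.copy()
    idx = np.arange(p, q)
    A_pen[idx, idx] += pen
    coef = cho_solve(cho_factor(A_pen, lower=True), bvec)
    beta_hat, b_hat = coef[:p], coef[p:]
    rss = float(s - 2.0 * coef @ bvec + coef @ (A @ coef))

    # subject-intercept EBLUPs: u_i = sigma_u^2 1' R_i^-1 (y_i - C_i theta)
    resid = y - design.C() @ coef
    Rin_resid = engine.solve_R(resid, vc)
    u = {
        subj: float(vc.sigma2_u * Rin_resid[sl].sum())
        for subj, sl in design.subject_slices.items()
    }

    flags = []
    for name, val in zip(_param_layout(design, cov_spec), np.exp(best.x)):
        if name != "tau" and val < BOUNDARY_TOL:
            flags.append(name)

    result = FitResult(
        method=method, model_spec=model_spec, cov_spec=cov_spec, design=design,
        varcomp=vc, beta=beta_hat, b=b_hat, u=u, minus2ll=float(minus2ll),
        converged=converged, n_iter=int(n_iter_total),
        boundary_flags=tuple(flags), y=y, A=A, bvec=bvec, penalty_diag=pen,
        rss_weighted=rss, engine=engine,
    )
    if not converged:
        raise ConvergenceError("variance-component optimization failed", best=result)
    return result


def eblup_coefficients(fit_result: FitResult):
    """(beta-hat, spline EBLUPs b-hat, subject-intercept EBLUPs u-hat)."""
    return fit_result.beta, fit_result.b, fit_result.u


def predict_curve(
    fit_result: FitResult,
    grid: np.ndarray,
    group: str,
    covariate_values: dict[str, float] | None = None,
) -> CurveTable:
    """Estimated group mean curve f_l(g) on a grid, covariates at zero.

    Extrapolation beyond the fitted time range is allowed but the truncated
    basis degrades quickly there; a warning is attached via numpy errstate
    semantics (callers should restrict grids to the observed range).
    """
    grid = np.asarray(grid, float).ravel()
    t = fit_result.design.times
    if grid.min() < t.min() - 1e-9 or grid.max() > t.max() + 1e-9:
        import warnings

        warnings.warn("grid extends beyond the fitted time range; extrapolating")
    Xg, Zg = build_curve_design(fit_result.design, grid, group, covariate_values)
    est = Xg @ fit_result.beta + Zg @ fit_result.b
    return CurveTable(grid=grid, label=group, estimate=est)
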