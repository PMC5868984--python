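"""Knot selection and truncated-power spline bases.

The mean curve f(t) is represented in a degree-p truncated power basis

    f(t) = beta_0 + beta_1 t + ... + beta_p t^p + sum_k b_k (t - kappa_k)_+^p

with (x)_+ = max(x, 0).  The polynomial part enters a model's fixed effects
(the intercept column is added by the design layer, not here) while the
truncated terms act as penalized spline coefficients, realized downstream as
Gaussian random effects.  Knots are placed at empirical quantiles of the
distinct observed times (the Ngo-Wand style automatic rule); the quantile
definition is numpy's default linear interpolation of order statistics.

A B-spline basis of the same degree and knots spans the same function space
and is provided for verification only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "KnotSet",
    "BasisSpec",
    "KnotSelectionError",
    "select_knots_quantile",
    "truncated_power_basis",
    "truncated_power_derivative",
    "bspline_basis",
]


class KnotSelectionError(ValueError):
    """Requested knots cannot be placed (too few distinct times, ties...)."""


@dataclass(frozen=True)
class KnotSet:
    """Strictly increasing interior knots kappa_1 < ... < kappa_K."""

    knots: tuple[float, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.knots, float)
        if arr.size and np.any(np.diff(arr) <= 0):
            raise KnotSelectionError(f"knots must be strictly increasing: {self.knots}")
        object.__setattr__(self, "knots", tuple(float(k) for k in arr))

    def __len__(self) -> int:
        return len(self.knots)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.knots, float)


@dataclass(frozen=True)
class BasisSpec:
    """Degree-p truncated power basis on a fixed knot set.

    ``degree`` in {1, 2, 3}; the case-study default is quadratic (p=2) with
    nine interior knots.  The spline-side column count equals the number of
    knots; polynomial columns are t, ..., t^p (no intercept).
    """

    degree: int = 2
    knots: KnotSet = field(default_factory=lambda: KnotSet(()))

    def __post_init__(self) -> None:
        if self.degree not in (1, 2, 3):
            raise ValueError(f"degree must be 1, 2 or 3, got {self.degree}")

    @property
    def n_poly(self) -> int:
        return self.degree

    @property
    def n_spline(self) -> int:
        return len(self.knots)


def select_knots_quantile(times: np.ndarray, n_knots: int) -> KnotSet:
    """Place ``n_knots`` knots at the j/(K+1) quantiles of the distinct times.

    Uses linear interpolation of order statistics (numpy's default quantile
    definition).  Raises :class:`KnotSelectionError` when there are too few
    distinct times or ties collapse the requested knots.
    """
    distinct = np.unique(np.asarray(times, float))
    if n_knots == 0:
        return KnotSet(())
    if distinct.size < n_knots + 2:
        raise KnotSelectionError(
            f"need at least {n_knots + 2} distinct times for {n_knots} knots, "
            f"got {distinct.size}"
        )
    probs = np.arange(1, n_knots + 1) / (n_knots + 1)
    knots = np.quantile(distinct, probs)
    if np.any(np.diff(knots) <= 0):
        raise KnotSelectionError(f"ties collapse the requested {n_knots} knots")
    if not (distinct.min() < knots[0] and knots[-1] < distinct.max()):
        raise KnotSelectionError("knots fall on the boundary of the observed times")
    return KnotSet(tuple(knots))


def truncated_power_basis(t: np.ndarray, spec: BasisSpec) -> np.ndarray:
    """Evaluate [t, ..., t^p, (t-kappa_1)_+^p, ..., (t-kappa_K)_+^p].

    Returns an (n, p + K) matrix; the intercept column is deliberately
    omitted (the design layer adds it once).
    """
    t = np.asarray(t, float).ravel()
    p = spec.degree
    poly = np.column_stack([t**j for j in range(1, p + 1)])
    if spec.n_spline == 0:
        return poly
    kappa = spec.knots.as_array()
    trunc = np.maximum(t[:, None] - kappa[None, :], 0.0) ** p
    return np.column_stack([poly, trunc])


def truncated_power_derivative(t: np.ndarray, spec: BasisSpec, order: int = 1) -> np.ndarray:
    """First-derivative basis matching :func:`truncated_power_basis` columns.

    Column for t^j maps to j t^(j-1); column for (t-kappa)_+^p maps to
    p (t-kappa)_+^(p-1), so the plug-in rule f'(t) = (derivative basis) @ coef
    holds with the fitted coefficients.  Only order 1 is supported.
    """
    if order != 1:
        raise NotImplementedError("only first derivatives are supported")
    t = np.asarray(t, float).ravel()
    p = spec.degree
    poly = np.column_stack([j * t ** (j - 1) for j in range(1, p + 1)])
    if spec.n_spline == 0:
        return poly
    kappa = spec.knots.as_array()
    trunc = p * np.maximum(t[:, None] - kappa[None, :], 0.0) ** (p - 1)
    return np.column_stack([poly, trunc])


def bspline_basis(t: np.ndarray, knots: KnotSet, degree: int, domain=None) -> np.ndarray:
    """B-spline design matrix of the same degree/knots (verification only).

    Spans the same space as intercept + :func:`truncated_power_basis`; used
    in tests to confirm basis-invariance of unpenalized fits, never in the
    fitting path.
    """
    t = np.asarray(t, float).ravel()
    lo, hi = (t.min(), t.max()) if domain is None else domain
    interior = knots.as_array()
    full = np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]
    n_basis = len(interior) + degree + 1
    out = np.empty((t.size, n_basis))
    for j in range(n_basis):
        coef = np.zeros(n_basis)
        coef[j] = 1.0
        out[:, j] = BSpline(full, coef, degree, extrapolate=False)(t)
    # right-closed support at the domain end
    out[np.isnan(out)] = 0.0
    at_hi = t == hi
    if at_hi.any():
        coef = np.zeros(n_basis)
        coef[-1] = 1.0
        out[at_hi, -1] = 1.0
    return out
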