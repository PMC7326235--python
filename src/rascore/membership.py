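"""Fuzzy membership functions over period count and age, and their fits.

Two membership functions are used. Over period counts, the proportion of
regular menstruators is approximated by a biquadratic exponential,

    fitted_P(period) = exp(c4*u^4 + c3*u^3 + c2*u^2 + c1*u + c0),
    u = period - shift,

and the membership in the "not regularly menstruating" set is
``mu_A = 1 - fitted_P``, clamped into [0, 1]. Over (modified) age, the
proportion with stopped menses is approximated by a quadratic logistic,

    mu_B(age) = expit(b2*age^2 + b1*age + b0).

The published coefficient sets ship as :data:`PUBLISHED_MU_A` and
:data:`PUBLISHED_MU_B`. Refits use unweighted nonlinear least squares in
probability space with a deterministic linearised initialisation; the
quartic family is closed under shift, so refits fix ``shift = 0`` while
the published parameter set keeps its 0.7 offset and is evaluated exactly
as printed.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit, logit

from .crosstab import GridKind, ProportionSeries

logger = logging.getLogger(__name__)

#: Period counts above this are clamped before evaluating mu_A: the
#: development data end at 15 periods/year and the quartic is
#: unconstrained beyond the observed range.
MU_A_PERIOD_MAX = 15


@dataclass(frozen=True)
class MuAParams:
    """Biquadratic exponential coefficients for the period-count curve."""

    shift: float
    c4: float
    c3: float
    c2: float
    c1: float
    c0: float

    def coefficients(self) -> tuple[float, ...]:
        return (self.c4, self.c3, self.c2, self.c1, self.c0)


@dataclass(frozen=True)
class MuBParams:
    """Quadratic logistic coefficients for the age curve."""

    b2: float
    b1: float
    b0: float

    def coefficients(self) -> tuple[float, ...]:
        return (self.b2, self.b1, self.b0)


#: Published coefficient sets of the development fit.
PUBLISHED_MU_A = MuAParams(shift=0.7, c4=-0.00047, c3=0.009, c2=-0.0307, c1=0.086, c0=-2.317)
PUBLISHED_MU_B = MuBParams(b2=0.0047, b1=-0.0866, b0=-7.646)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a membership-curve fit.

    ``mse`` is the unweighted mean of squared residuals in probability
    space over the ``n_points`` fitted grid points.
    """

    params: "MuAParams | MuBParams"
    mse: float
    n_points: int
    converged: bool


def _check_finite(values, what: str) -> None:
    if not all(math.isfinite(v) for v in values):
        raise ValueError(f"non-finite {what} coefficient")


def fitted_p_period(period, params: MuAParams):
    """The biquadratic exponential approximation of P(period), unclamped."""
    _check_finite(params.coefficients() + (params.shift,), "mu_A")
    u = np.asarray(period, dtype=float) - params.shift
    return np.exp(np.polyval(params.coefficients(), u))


def eval_mu_a(period, params: MuAParams = PUBLISHED_MU_A):
    """Membership in the not-regularly-menstruating set, in [0, 1].

    Periods above 15/year are clamped to 15 (with a warning) before
    evaluation; the raw value ``1 - fitted_P`` is clamped into [0, 1]
    afterwards, since the published coefficients make the exponential
    slightly exceed 1 near 12-13 periods.
    """
    period = np.asarray(period, dtype=float)
    if np.any(period < 0):
        raise ValueError("period count must be >= 0")
    if np.any(period > MU_A_PERIOD_MAX):
        logger.warning(
            "period counts above %d clamped for mu_A evaluation", MU_A_PERIOD_MAX
        )
        period = np.minimum(period, MU_A_PERIOD_MAX)
    raw = 1.0 - fitted_p_period(period, params)
    return np.clip(raw, 0.0, 1.0)[()]


def eval_mu_b(m_age, params: MuBParams = PUBLISHED_MU_B):
    """Membership in the stopped-menses set at (modified) age, in (0, 1)."""
    _check_finite(params.coefficients(), "mu_B")
    m_age = np.asarray(m_age, dtype=float)
    if np.any(m_age < 0):
        raise ValueError("age must be >= 0")
    if np.any((m_age < 35) | (m_age > 70)):
        logger.warning("age outside the 35-70 development range; extrapolating")
    q = np.polyval(params.coefficients(), m_age)
    return expit(q)[()]


def _series_arrays(series: ProportionSeries, kind: GridKind):
    if series.kind is not kind:
        raise ValueError(f"expected a {kind.value} proportion series")
    return np.asarray(series.grid, float), np.asarray(series.proportions, float)


def fit_mu_a(series: ProportionSeries) -> FitResult:
    """Fit the biquadratic exponential to a P(period) series.

    Minimises the unweighted sum of ``(exp(quartic) - P)^2`` over the grid.
    Initialisation is ordinary least squares of log P on the quartic basis
    over points with P strictly inside (0, 1), followed by
    Levenberg-Marquardt refinement in probability space.
    """
    grid, p = _series_arrays(series, GridKind.PERIODS)
    if len(grid) < 6:
        raise ValueError("need at least 6 grid points to fit mu_A")

    interior = (p > 0) & (p < 1)
    basis = np.vander(grid[interior], 5)
    x0 = np.linalg.lstsq(basis, np.log(p[interior]), rcond=None)[0]

    def residuals(c):
        return np.exp(np.polyval(c, grid)) - p

    sol = least_squares(residuals, x0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=50000)
    params = MuAParams(0.0, *(float(v) for v in sol.x))
    mse = float(np.mean(sol.fun**2))
    if not sol.success:
        logger.warning("mu_A fit did not converge: %s", sol.message)
    return FitResult(params=params, mse=mse, n_points=len(grid), converged=bool(sol.success))


def fit_mu_b(series: ProportionSeries) -> FitResult:
    """Fit the quadratic logistic to a P(age) series.

    Minimises the unweighted sum of ``(expit(quadratic) - P)^2``; the
    start point is ordinary least squares of logit P on the quadratic
    basis over interior points.
    """
    grid, p = _series_arrays(series, GridKind.AGE)
    if len(grid) < 4:
        raise ValueError("need at least 4 grid points to fit mu_B")

    interior = (p > 0) & (p < 1)
    basis = np.vander(grid[interior], 3)
    x0 = np.linalg.lstsq(basis, logit(p[interior]), rcond=None)[0]

    def residuals(b):
        return expit(np.polyval(b, grid)) - p

    sol = least_squares(residuals, x0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=50000)
    params = MuBParams(*(float(v) for v in sol.x))
    mse = float(np.mean(sol.fun**2))
    if not sol.success:
        logger.warning("mu_B fit did not converge: %s", sol.message)
    return FitResult(params=params, mse=mse, n_points=len(grid), converged=bool(sol.success))


def mse_against_series(params, series: ProportionSeries) -> float:
    """Unweighted MSE of a parameter set against a proportion series.

    For a period series the residual is ``fitted_P - P`` (the same
    objective the fit minimises, without clamping); for an age series it
    is ``mu_B - P``.
    """
    if isinstance(params, MuAParams):
        grid, p = _series_arrays(series, GridKind.PERIODS)
        fitted = fitted_p_period(grid, params)
    elif isinstance(params, MuBParams):
        grid, p = _series_arrays(series, GridKind.AGE)
        fitted = eval_mu_b(grid, params)
    else:
        raise TypeError(f"unsupported parameter set {type(params).__name__}")
    return float(np.mean((fitted - p) ** 2))
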