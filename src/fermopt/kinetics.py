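"""Batch-fermentation growth and production kinetics.

Biomass follows the logistic model

    X(t) = X0 Xmax e^(mu t) / (Xmax - X0 + X0 e^(mu t)),

with initial biomass X0 (g/L), carrying capacity Xmax (g/L) and maximum
specific growth rate mu_max (1/h).  Product formation, enzyme activity and
cumulative substrate consumption follow the modified Gompertz model

    P(t) = Pmax exp(-exp(r_max e / Pmax * (t_lag - t) + 1)),

parameterized directly by the asymptote Pmax, the maximum volumetric rate
r_max (slope at the inflection) and the lag time t_lag (where the inflection
tangent crosses zero).  Both are fitted by bounded nonlinear least squares
from data-driven starting values, and yield coefficients are derived from the
fitted asymptotes and rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize as _sciopt
from scipy import stats

__all__ = ["LogisticParams", "GompertzParams", "FitStats", "YieldCoefficients",
           "logistic_curve", "gompertz_curve", "fit_timeseries", "derive_yields"]

_E = float(np.e)


@dataclass(frozen=True)
class LogisticParams:
    X0: float
    Xmax: float
    mu_max: float

    def __post_init__(self) -> None:
        if not (0 < self.X0 < self.Xmax):
            raise ValueError("require 0 < X0 < Xmax")
        if self.mu_max <= 0:
            raise ValueError("mu_max must be positive")


@dataclass(frozen=True)
class GompertzParams:
    Pmax: float
    r_max: float
    t_lag: float

    def __post_init__(self) -> None:
        if self.Pmax <= 0 or self.r_max <= 0:
            raise ValueError("Pmax and r_max must be positive")
        if self.t_lag < 0:
            raise ValueError("t_lag must be non-negative")


@dataclass(frozen=True)
class FitStats:
    r2: float
    adj_r2: float
    rmse: float
    mae: float
    p_value: float      # F test against the constant model


@dataclass(frozen=True)
class YieldCoefficients:
    Yp_s: float     # product per substrate (mg/g by default units)
    Yx_s: float     # biomass per substrate (g/g)
    Yp_x: float     # product per biomass (g/g)
    q_p: float      # specific production rate (mg/gDCW/h)
    q_s: float      # specific substrate-consumption rate (g/gDCW/h)


def logistic_curve(t, p: LogisticParams):
    """Logistic biomass curve; X(0) = X0, X(inf) = Xmax, inflection at Xmax/2."""
    t = np.asarray(t, dtype=float)
    # algebraically X0*Xmax*e^{mu t} / (Xmax - X0 + X0 e^{mu t}); written with
    # e^{-mu t} so large t cannot overflow
    return p.X0 * p.Xmax / (p.X0 + (p.Xmax - p.X0) * np.exp(-p.mu_max * t))


def gompertz_curve(t, p: GompertzParams):
    """Modified Gompertz curve; max slope r_max, inflection tangent hits 0 at t_lag."""
    t = np.asarray(t, dtype=float)
    inner = p.r_max * _E / p.Pmax * (p.t_lag - t) + 1.0
    return p.Pmax * np.exp(-np.exp(inner))


def _gof(t, y, yhat, n_params: int) -> FitStats:
    n = len(y)
    e = y - yhat
    sse = float(e @ e)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst
    dof = n - n_params
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1) if n - n_params - 1 > 0 else np.nan
    if sse > 0 and dof > 0:
        F = ((sst - sse) / (n_params - 1)) / (sse / dof)
        p = float(stats.f.sf(F, n_params - 1, dof))
    else:
        p = 0.0
    return FitStats(r2=r2, adj_r2=adj, rmse=float(np.sqrt(sse / n)),
                    mae=float(np.abs(e).mean()), p_value=p)


def _logistic_start(t, y):
    x0 = max(y[0], 1e-6 * y.max())
    xmax = 1.05 * y.max()
    dy = np.diff(y) / np.diff(t)
    i = int(np.argmax(dy))
    # at the inflection dX/dt = mu*Xmax/4
    mu = max(4.0 * dy[i] / xmax, 1e-3)
    return [x0, xmax, mu]


def _gompertz_start(t, y):
    pmax = 1.05 * y.max()
    dy = np.diff(y) / np.diff(t)
    i = int(np.argmax(dy))
    r = max(dy[i], 1e-6 * pmax)
    tm = 0.5 * (t[i] + t[i + 1])
    ym = 0.5 * (y[i] + y[i + 1])
    t_lag = max(tm - ym / r, 0.0)
    return [pmax, r, t_lag]


def fit_timeseries(t, y, model: str):
    """Nonlinear least-squares fit of a growth/production curve.

    Returns ``(params, stats)`` where params is :class:`LogisticParams` or
    :class:`GompertzParams` and stats a :class:`FitStats`.  Starting values
    come from the data (first/maximum observation, steepest finite-difference
    slope, tangent-intercept lag); positivity is enforced through bounds.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) != len(y):
        raise ValueError("t and y must have equal length")
    if len(t) < 5:
        raise ValueError("need at least 5 time points")
    if np.any(y < 0):
        raise ValueError("negative observations are not valid concentrations")
    if np.ptp(y) == 0:
        raise ValueError("constant series: kinetic parameters unidentifiable")

    if model == "logistic":
        def f(tt, x0, xmax, mu):
            return x0 * xmax / (x0 + (xmax - x0) * np.exp(-mu * tt))
        start = _logistic_start(t, y)
        lower = [1e-12, 1e-12, 1e-12]
        upper = [np.inf, np.inf, np.inf]
    elif model == "gompertz":
        def f(tt, pmax, r, tl):
            return pmax * np.exp(-np.exp(r * _E / pmax * (tl - tt) + 1.0))
        start = _gompertz_start(t, y)
        lower = [1e-12, 1e-12, 0.0]
        upper = [np.inf, np.inf, np.inf]
    else:
        raise ValueError(f"unknown model {model!r}")

    try:
        popt, _ = _sciopt.curve_fit(f, t, y, p0=start, bounds=(lower, upper),
                                    maxfev=20000, ftol=1e-12, xtol=1e-12, gtol=1e-12)
    except RuntimeError as err:
        raise RuntimeError(f"{model} fit did not converge from start {start}: {err}") from err

    yhat = f(t, *popt)
    stats_ = _gof(t, y, yhat, 3)
    if model == "logistic":
        x0, xmax, mu = popt
        x0 = min(x0, xmax * (1 - 1e-12))  # guard the X0 < Xmax invariant at fit edge
        return LogisticParams(float(x0), float(xmax), float(mu)), stats_
    pmax, r, tl = popt
    return GompertzParams(float(pmax), float(r), float(tl)), stats_


def derive_yields(logistic: LogisticParams, product: GompertzParams,
                  substrate: GompertzParams, *, product_unit: str = "mg",
                  biomass_unit: str = "g", substrate_unit: str = "g") -> YieldCoefficients:
    """Yield and specific-rate coefficients from fitted asymptotes.

    Conventions: Yp_s = Pmax/Smax (product units per substrate unit),
    Yx_s = (Xmax - X0)/Smax, Yp_x = product (converted to biomass units) per
    Xmax, and the specific rates divide each maximum volumetric rate by the
    biomass capacity, q = r_max/Xmax.
    """
    if product_unit not in ("mg", "g") or biomass_unit != "g" or substrate_unit != "g":
        raise ValueError("supported units: product mg or g; biomass g; substrate g")
    to_g = 1e-3 if product_unit == "mg" else 1.0
    smax = substrate.Pmax
    return YieldCoefficients(
        Yp_s=product.Pmax / smax,
        Yx_s=(logistic.Xmax - logistic.X0) / smax,
        Yp_x=product.Pmax * to_g / logistic.Xmax,
        q_p=product.r_max / logistic.Xmax,
        q_s=substrate.r_max / logistic.Xmax,
    )
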