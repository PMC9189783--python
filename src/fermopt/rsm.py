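"""Second-order response-surface regression with lack-of-fit ANOVA.

The response is modelled as a full quadratic polynomial in the k design
factors,

    y = b0 + sum_i bi xi + sum_{i<j} bij xi xj + sum_i bii xi^2 + e,

fitted by ordinary least squares (1 + 2k + k(k-1)/2 terms; 21 for k = 5).
Replicated design points provide a pure-error estimate, so model inadequacy
can be tested with the standard lack-of-fit F ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .doe import DesignMatrix

__all__ = ["SurfaceFit", "AnovaTable", "quadratic_terms", "term_names",
           "fit_quadratic", "anova"]


def quadratic_terms(X: np.ndarray) -> np.ndarray:
    """Design matrix of the full quadratic basis: 1, xi, xi*xj (i<j), xi^2."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, k = X.shape
    cols = [np.ones(n)]
    cols += [X[:, i] for i in range(k)]
    cols += [X[:, i] * X[:, j] for i in range(k) for j in range(i + 1, k)]
    cols += [X[:, i] ** 2 for i in range(k)]
    return np.column_stack(cols)


def term_names(names: list[str]) -> list[str]:
    k = len(names)
    out = ["intercept"] + list(names)
    out += [f"{names[i]}*{names[j]}" for i in range(k) for j in range(i + 1, k)]
    out += [f"{n}^2" for n in names]
    return out


@dataclass
class SurfaceFit:
    """Coefficients of a fitted (or externally supplied) quadratic surface.

    Coefficient layout follows :func:`quadratic_terms`: intercept, k linear,
    k(k-1)/2 interactions in (i<j) order, k pure quadratics.  ``basis``
    records whether the coefficients apply to coded or actual factor levels.
    """

    k: int
    intercept: float
    linear: np.ndarray
    interaction: np.ndarray
    quadratic: np.ndarray
    basis: str = "coded"
    names: list[str] = field(default_factory=list)
    r2: float = float("nan")
    adj_r2: float = float("nan")
    se: np.ndarray | None = None
    pvalues: np.ndarray | None = None
    residuals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.linear = np.asarray(self.linear, dtype=float)
        self.interaction = np.asarray(self.interaction, dtype=float)
        self.quadratic = np.asarray(self.quadratic, dtype=float)
        expected = self.k * (self.k - 1) // 2
        if len(self.linear) != self.k or len(self.quadratic) != self.k:
            raise ValueError("linear/quadratic coefficient length must equal k")
        if len(self.interaction) != expected:
            raise ValueError(f"expected {expected} interaction coefficients")

    @property
    def coef(self) -> np.ndarray:
        return np.concatenate([[self.intercept], self.linear, self.interaction, self.quadratic])

    @property
    def n_terms(self) -> int:
        return 1 + 2 * self.k + self.k * (self.k - 1) // 2

    def predict(self, points: np.ndarray) -> np.ndarray:
        """Evaluate the surface at one point (length k) or many (n x k)."""
        points = np.asarray(points, dtype=float)
        single = points.ndim == 1
        out = quadratic_terms(np.atleast_2d(points)) @ self.coef
        return float(out[0]) if single else out

    @classmethod
    def from_coefficients(cls, intercept: float, linear, interaction, quadratic,
                          basis: str = "coded", names: list[str] | None = None) -> "SurfaceFit":
        linear = np.asarray(linear, dtype=float)
        return cls(k=len(linear), intercept=float(intercept), linear=linear,
                   interaction=interaction, quadratic=quadratic, basis=basis,
                   names=names or [])

    def to_dict(self) -> dict:
        out = {"k": self.k, "basis": self.basis, "names": self.names,
               "intercept": self.intercept, "linear": self.linear.tolist(),
               "interaction": self.interaction.tolist(),
               "quadratic": self.quadratic.tolist()}
        if np.isfinite(self.r2):  # absent for externally supplied coefficients
            out["r2"] = self.r2
            out["adj_r2"] = self.adj_r2
        return out


@dataclass
class AnovaTable:
    """Sequential variance decomposition with replicate-based lack of fit."""

    ss_model: float
    ss_residual: float
    ss_total: float
    df_model: int
    df_residual: int
    df_total: int
    f_model: float
    p_model: float
    ss_lof: float | None = None
    ss_pe: float | None = None
    df_lof: int | None = None
    df_pe: int | None = None
    f_lof: float | None = None
    p_lof: float | None = None

    @property
    def lack_of_fit_available(self) -> bool:
        return self.f_lof is not None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("model", self.ss_model, self.df_model, self.ss_model / self.df_model,
             self.f_model, self.p_model),
            ("residual", self.ss_residual, self.df_residual,
             self.ss_residual / self.df_residual if self.df_residual else np.nan,
             np.nan, np.nan),
        ]
        if self.lack_of_fit_available:
            rows += [
                ("lack_of_fit", self.ss_lof, self.df_lof, self.ss_lof / self.df_lof,
                 self.f_lof, self.p_lof),
                ("pure_error", self.ss_pe, self.df_pe,
                 self.ss_pe / self.df_pe if self.df_pe else np.nan, np.nan, np.nan),
            ]
        rows.append(("total", self.ss_total, self.df_total, np.nan, np.nan, np.nan))
        return pd.DataFrame(rows, columns=["source", "ss", "df", "ms", "F", "p"])


def _design_levels(design, basis: str) -> tuple[np.ndarray, list[str]]:
    if isinstance(design, DesignMatrix):
        X = design.coded if basis == "coded" else design.actual
        return X, design.factors.names
    X = np.asarray(design, dtype=float)
    return X, [f"x{i+1}" for i in range(X.shape[1])]


def fit_quadratic(design, y: np.ndarray, *, basis: str = "coded") -> SurfaceFit:
    """OLS fit of the full quadratic surface.

    ``design`` may be a :class:`~fermopt.doe.DesignMatrix` (levels taken in the
    requested basis) or a plain n x k array already in that basis.
    """
    y = np.asarray(y, dtype=float)
    X, names = _design_levels(design, basis)
    n, k = X.shape
    A = quadratic_terms(X)
    p = A.shape[1]
    if n <= p:
        raise ValueError(f"{n} runs cannot support a {p}-term quadratic model")
    if np.linalg.matrix_rank(A) < p:
        raise ValueError("quadratic basis is singular on this design")
    res = sm.OLS(y, A).fit()
    beta = res.params
    n_int = k * (k - 1) // 2
    fit = SurfaceFit(
        k=k, intercept=float(beta[0]), linear=beta[1:1 + k],
        interaction=beta[1 + k:1 + k + n_int], quadratic=beta[1 + k + n_int:],
        basis=basis, names=names,
        r2=float(res.rsquared), adj_r2=float(res.rsquared_adj),
        se=np.asarray(res.bse), pvalues=np.asarray(res.pvalues),
        residuals=np.asarray(res.resid),
    )
    return fit


def anova(fit: SurfaceFit, design, y: np.ndarray) -> AnovaTable:
    """ANOVA of a fitted surface; pure error comes from replicated design points.

    With m distinct design points and p model terms the lack-of-fit F ratio is
    MS_lof / MS_pe on (m - p, n - m) degrees of freedom.  Without replicates
    the decomposition stops at the residual line.
    """
    y = np.asarray(y, dtype=float)
    X, _ = _design_levels(design, fit.basis)
    n = len(y)
    p = fit.n_terms
    resid = y - fit.predict(X)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    ss_mod = ss_tot - ss_res
    df_mod, df_res = p - 1, n - p
    ms_mod = ss_mod / df_mod
    ms_res = ss_res / df_res
    f_mod = ms_mod / ms_res
    p_mod = float(stats.f.sf(f_mod, df_mod, df_res))
    table = AnovaTable(ss_model=ss_mod, ss_residual=ss_res, ss_total=ss_tot,
                       df_model=df_mod, df_residual=df_res, df_total=n - 1,
                       f_model=f_mod, p_model=p_mod)

    groups: dict[tuple, list[int]] = {}
    for i, row in enumerate(np.round(np.atleast_2d(X), 10)):
        groups.setdefault(tuple(row), []).append(i)
    df_pe = n - len(groups)
    if df_pe <= 0:
        return table  # no replicates: lack of fit unavailable
    ss_pe = float(sum(((y[idx] - y[idx].mean()) ** 2).sum()
                      for idx in (np.array(g) for g in groups.values())))
    ss_lof = ss_res - ss_pe
    df_lof = len(groups) - p
    table.ss_pe, table.df_pe = ss_pe, df_pe
    table.ss_lof, table.df_lof = ss_lof, df_lof
    if df_lof > 0 and ss_pe > 0:
        table.f_lof = (ss_lof / df_lof) / (ss_pe / df_pe)
        table.p_lof = float(stats.f.sf(table.f_lof, df_lof, df_pe))
    return table
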