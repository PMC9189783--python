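"""Two-level factorial and central composite designs with coded-level algebra.

A medium-optimization experiment varies k nutrient factors around a base
composition.  Each factor is handled on a *coded* scale where the factorial
low/high map to -1/+1 and the centre of the range to 0; designs are generated
in coded units and converted back to actual concentrations through the affine
map stored in a :class:`FactorSet`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml

__all__ = [
    "Factor",
    "FactorSet",
    "DesignMatrix",
    "FirstOrderFit",
    "two_level_factorial",
    "ccrd",
    "rotatable_alpha",
    "fit_first_order",
    "steepest_ascent_path",
]


@dataclass(frozen=True)
class Factor:
    """One design factor with its -1/+1 actual levels."""

    name: str
    low: float
    high: float
    units: str = ""

    def __post_init__(self) -> None:
        if not self.high > self.low:
            raise ValueError(f"factor {self.name!r}: high ({self.high}) must exceed low ({self.low})")

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high - self.low)


class FactorSet:
    """Ordered collection of factors defining the coded <-> actual affine map."""

    def __init__(self, factors: Sequence[Factor]):
        factors = list(factors)
        if len(factors) < 2:
            raise ValueError("a factor set needs at least 2 factors")
        names = [f.name for f in factors]
        if len(set(names)) != len(names):
            raise ValueError("factor names must be unique")
        self.factors = factors

    def __len__(self) -> int:
        return len(self.factors)

    def __iter__(self):
        return iter(self.factors)

    def __getitem__(self, i: int) -> Factor:
        return self.factors[i]

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def centers(self) -> np.ndarray:
        return np.array([f.center for f in self.factors])

    @property
    def half_ranges(self) -> np.ndarray:
        return np.array([f.half_range for f in self.factors])

    def code(self, actual: np.ndarray) -> np.ndarray:
        """Map actual levels (last axis = factors) to coded units."""
        actual = np.asarray(actual, dtype=float)
        if actual.shape[-1] != len(self):
            raise ValueError(f"expected {len(self)} factor values, got {actual.shape[-1]}")
        return (actual - self.centers) / self.half_ranges

    def decode(self, coded: np.ndarray) -> np.ndarray:
        """Map coded levels back to actual units."""
        coded = np.asarray(coded, dtype=float)
        if coded.shape[-1] != len(self):
            raise ValueError(f"expected {len(self)} coded values, got {coded.shape[-1]}")
        return self.centers + coded * self.half_ranges

    @classmethod
    def from_yaml(cls, path) -> "FactorSet":
        with open(path) as fh:
            spec = yaml.safe_load(fh)
        return cls([Factor(d["name"], float(d["low"]), float(d["high"]), d.get("units", ""))
                    for d in spec["factors"]])

    def to_dict(self) -> dict:
        return {"factors": [{"name": f.name, "low": f.low, "high": f.high, "units": f.units}
                            for f in self.factors]}


@dataclass
class DesignMatrix:
    """Runs of an experimental design, kept in coded units.

    ``point_class`` labels each row ``factorial``, ``axial`` or ``center``;
    ``replicate_groups`` partitions row indices by identical coded levels and
    is what the lack-of-fit ANOVA uses for pure error.
    """

    factors: FactorSet
    coded: np.ndarray
    point_class: np.ndarray

    def __post_init__(self) -> None:
        self.coded = np.asarray(self.coded, dtype=float)
        self.point_class = np.asarray(self.point_class, dtype=object)
        if self.coded.ndim != 2 or self.coded.shape[1] != len(self.factors):
            raise ValueError("coded matrix must be n_runs x k")
        if len(self.point_class) != len(self.coded):
            raise ValueError("point_class length mismatch")

    def __len__(self) -> int:
        return len(self.coded)

    @property
    def actual(self) -> np.ndarray:
        return self.factors.decode(self.coded)

    @property
    def replicate_groups(self) -> dict[tuple, list[int]]:
        groups: dict[tuple, list[int]] = {}
        for i, row in enumerate(np.round(self.coded, 10)):
            groups.setdefault(tuple(row), []).append(i)
        return groups

    @property
    def n_distinct(self) -> int:
        return len(self.replicate_groups)

    def to_frame(self, actual: bool = True) -> pd.DataFrame:
        levels = self.actual if actual else self.coded
        df = pd.DataFrame(levels, columns=self.factors.names)
        df.insert(0, "run", np.arange(1, len(self) + 1))
        df["point_class"] = self.point_class
        return df

    @classmethod
    def from_actual(cls, factors: FactorSet, actual: np.ndarray,
                    alpha: float | None = None) -> "DesignMatrix":
        """Classify rows of an actual-level matrix by inspecting coded levels."""
        coded = np.round(factors.code(np.asarray(actual, dtype=float)), 10)
        classes = []
        for row in coded:
            nonzero = row[row != 0]
            if nonzero.size == 0:
                classes.append("center")
            elif np.all(np.abs(row) == 1):
                classes.append("factorial")
            elif nonzero.size == 1 and (alpha is None or np.isclose(abs(nonzero[0]), alpha)):
                classes.append("axial")
            else:
                classes.append("other")
        return cls(factors, coded, np.array(classes, dtype=object))


def two_level_factorial(factors: FactorSet) -> DesignMatrix:
    """Full 2^k design in standard (Yates) order, all coded entries +/-1."""
    k = len(factors)
    if k > 12:
        raise ValueError(f"2^{k} runs is beyond the supported full-factorial size (k <= 12)")
    # Yates order: first factor alternates fastest
    grids = np.meshgrid(*([np.array([-1.0, 1.0])] * k), indexing="ij")
    coded = np.column_stack([g.reshape(-1, order="F") for g in grids])
    return DesignMatrix(factors, coded, np.array(["factorial"] * 2**k, dtype=object))


def rotatable_alpha(n_factorial: int) -> float:
    """Axial distance giving a rotatable central composite design, F**(1/4)."""
    return float(n_factorial) ** 0.25


def ccrd(factors: FactorSet, n_center: int = 8,
         alpha: float | Literal["rotatable"] = 2.0) -> DesignMatrix:
    """Central composite design: 2^k corners + 2k axial points + centre replicates.

    ``alpha`` is the coded axial distance; ``"rotatable"`` uses F**(1/4) where
    F is the number of factorial points.  Axial actual levels are
    centre +/- alpha * half_range.
    """
    if n_center < 1:
        raise ValueError("n_center must be >= 1")
    k = len(factors)
    fact = two_level_factorial(factors)
    if alpha == "rotatable":
        alpha = rotatable_alpha(len(fact))
    alpha = float(alpha)
    if alpha <= 1:
        raise ValueError("alpha must exceed 1 (axial points lie outside the cube)")
    axial = np.zeros((2 * k, k))
    for i in range(k):
        axial[2 * i, i] = -alpha
        axial[2 * i + 1, i] = alpha
    center = np.zeros((n_center, k))
    coded = np.vstack([fact.coded, axial, center])
    classes = np.array(["factorial"] * len(fact) + ["axial"] * (2 * k)
                       + ["center"] * n_center, dtype=object)
    return DesignMatrix(factors, coded, classes)


@dataclass
class FirstOrderFit:
    """First-order (optionally with two-way interactions) screening fit in coded units."""

    intercept: float
    coef: np.ndarray            # linear terms, length k
    se: np.ndarray
    pvalues: np.ndarray
    significant: np.ndarray     # boolean, p < threshold
    threshold: float
    names: list[str] = field(default_factory=list)
    interaction_coef: dict[tuple[int, int], float] = field(default_factory=dict)
    residual_sd: float = float("nan")


def fit_first_order(design: DesignMatrix, y: np.ndarray, *,
                    interactions: bool = False, threshold: float = 0.05) -> FirstOrderFit:
    """Least-squares first-order model on coded levels; flags p < threshold factors."""
    y = np.asarray(y, dtype=float)
    Z = design.coded
    n, k = Z.shape
    cols = [Z]
    pairs: list[tuple[int, int]] = []
    if interactions:
        pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
        cols.append(np.column_stack([Z[:, i] * Z[:, j] for i, j in pairs]))
    X = sm.add_constant(np.column_stack(cols))
    if n < X.shape[1]:
        raise ValueError(f"{n} runs cannot identify {X.shape[1]} parameters")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design is rank deficient for the requested model")
    res = sm.OLS(y, X).fit()
    coef = res.params[1:k + 1]
    inter = {p: res.params[k + 1 + m] for m, p in enumerate(pairs)}
    dof = n - X.shape[1]
    pvals = res.pvalues[1:k + 1] if dof > 0 else np.ones(k)
    return FirstOrderFit(
        intercept=float(res.params[0]),
        coef=np.asarray(coef),
        se=np.asarray(res.bse[1:k + 1]) if dof > 0 else np.full(k, np.nan),
        pvalues=np.asarray(pvals),
        significant=np.asarray(pvals) < threshold,
        threshold=threshold,
        names=design.factors.names,
        interaction_coef=inter,
        residual_sd=float(np.sqrt(res.mse_resid)) if dof > 0 else 0.0,
    )


def steepest_ascent_path(fit: FirstOrderFit, factors: FactorSet, base: np.ndarray, *,
                         step_size: float = 1.0, n_steps: int = 10,
                         reference: int | Literal["auto"] = "auto") -> pd.DataFrame:
    """Candidate medium compositions stepped along the fitted gradient.

    Step j moves each significant factor i by ``j * step_size * b_i / |b_ref|``
    coded units from ``base`` (actual units); non-significant factors stay at
    base.  The reference factor defaults to the one with the largest |coefficient|.
    """
    if not fit.significant.any():
        raise ValueError("no significant factors: steepest-ascent direction undefined")
    b = np.where(fit.significant, fit.coef, 0.0)
    if np.all(b == 0):
        raise ValueError("all significant coefficients are zero")
    if reference == "auto":
        reference = int(np.argmax(np.abs(b)))
    b_ref = abs(b[reference])
    if b_ref == 0:
        raise ValueError("reference factor has zero coefficient")
    direction = b / b_ref
    base = np.asarray(base, dtype=float)
    base_coded = factors.code(base)
    rows = []
    for j in range(n_steps + 1):
        coded = base_coded + j * step_size * direction
        rows.append(factors.decode(coded))
    out = pd.DataFrame(rows, columns=factors.names)
    out.insert(0, "step", np.arange(n_steps + 1))
    return out
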