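"""Locate the optimum of a fitted response surface and confirm it experimentally.

A linear maximize-type desirability rescales the predicted response to [0, 1];
the optimum is found by a coarse grid scan over the coded design box followed
by a local polish (L-BFGS-B).  A confirmation run ratifies the model when the
observed response lies within a set percentage (default 5%) of the prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize as _sciopt

from .rsm import SurfaceFit

__all__ = ["OptimizationResult", "ValidationVerdict", "desirability_maximize",
           "optimize_surface", "validate_optimum"]


def desirability_maximize(y, L: float, T: float):
    """Linear maximize desirability: 0 at/below L, 1 at/above T, linear between."""
    if not T > L:
        raise ValueError("target T must exceed lower bound L")
    return np.clip((np.asarray(y, dtype=float) - L) / (T - L), 0.0, 1.0)


@dataclass
class OptimizationResult:
    x_coded: np.ndarray
    x_actual: np.ndarray | None
    predicted: float
    desirability: float
    trace: list = field(default_factory=list)   # (stage, x, value)

    def to_dict(self) -> dict:
        return {"x_coded": self.x_coded.tolist(),
                "x_actual": None if self.x_actual is None else self.x_actual.tolist(),
                "predicted": self.predicted, "desirability": self.desirability}


def optimize_surface(fit: SurfaceFit, bounds=(-1.0, 1.0), *, grid_density: int = 5,
                     refine: bool = True, factors=None,
                     desirability_range: tuple[float, float] | None = None) -> OptimizationResult:
    """Maximize a quadratic surface over a coded box.

    ``bounds`` is either a (lo, hi) pair applied to every factor or a list of
    per-factor pairs.  A full grid of ``grid_density`` levels per factor seeds
    a bounded quasi-Newton polish.  Deterministic.  ``desirability_range``
    fixes the (L, T) anchors of the reported desirability; it defaults to the
    surface value range seen on the grid.
    """
    k = fit.k
    if np.ndim(bounds) == 1:
        bounds = [tuple(bounds)] * k
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi)) and np.all(hi > lo)):
        raise ValueError("bounds must be finite with hi > lo")

    axes = [np.linspace(lo[i], hi[i], grid_density) for i in range(k)]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([m.ravel() for m in mesh])
    vals = fit.predict(pts)
    i_best = int(np.argmax(vals))
    x_best, v_best = pts[i_best], float(vals[i_best])
    trace = [("grid", x_best.copy(), v_best)]

    if refine:
        res = _sciopt.minimize(lambda z: -fit.predict(z), x_best,
                               bounds=list(zip(lo, hi)), method="L-BFGS-B")
        if -res.fun > v_best:
            x_best, v_best = np.asarray(res.x), float(-res.fun)
        trace.append(("polish", x_best.copy(), v_best))

    if desirability_range is None:
        L, T = float(vals.min()), float(max(vals.max(), v_best))
    else:
        L, T = desirability_range
    d = 1.0 if T == L else float(desirability_maximize(v_best, L, T))
    x_actual = factors.decode(x_best) if factors is not None else None
    return OptimizationResult(x_coded=x_best, x_actual=x_actual,
                              predicted=v_best, desirability=d, trace=trace)


@dataclass(frozen=True)
class ValidationVerdict:
    predicted: float
    observed: float
    percent_difference: float
    threshold: float
    passed: bool


def validate_optimum(predicted: float, observed: float,
                     threshold: float = 5.0) -> ValidationVerdict:
    """Confirmation rule: |observed - predicted| / predicted * 100 < threshold."""
    if predicted <= 0:
        raise ValueError("predicted response must be positive")
    pct = 100.0 * abs(observed - predicted) / predicted
    return ValidationVerdict(predicted=float(predicted), observed=float(observed),
                             percent_difference=pct, threshold=threshold,
                             passed=pct < threshold)
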