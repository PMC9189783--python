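"""Seeded synthetic data with the statistical structure the analysis assumes.

Two generators stand in for the wet lab:

* :func:`simulate_doe` draws design-of-experiment responses from a known
  quadratic surface plus additive Gaussian noise (measurement error of a
  plate/flask assay is roughly homoscedastic across the narrow design region);
* :func:`simulate_fermentation` draws 0-36 h bioreactor time courses from
  logistic/modified-Gompertz dynamics with multiplicative Gaussian noise
  (sampling error scales with signal over the decades spanned by a batch run),
  floored at zero.

The default parameter presets are the fitted values of the packaged study
tables (mutant and wild-type strains), so tests exercise the pipeline under
the conditions the original experiment reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import datasets
from .doe import DesignMatrix
from .kinetics import (GompertzParams, LogisticParams, gompertz_curve,
                       logistic_curve)
from .rsm import SurfaceFit

__all__ = ["SurfaceTruth", "FermentationTruth", "simulate_doe",
           "simulate_fermentation", "surface_truth_preset",
           "fermentation_truth_preset"]

DEFAULT_TIMES = np.arange(0.0, 40.0, 4.0)   # 0, 4, ..., 36 h sampling grid


@dataclass
class SurfaceTruth:
    """A known quadratic response surface plus additive noise level."""

    surface: SurfaceFit
    noise_sd: float = 0.0
    seed: int = 0


@dataclass
class FermentationTruth:
    """True kinetic parameters for each measured series plus relative noise."""

    biomass: LogisticParams
    series: dict[str, GompertzParams] = field(default_factory=dict)
    times: np.ndarray = field(default_factory=lambda: DEFAULT_TIMES.copy())
    rel_noise_sd: float = 0.0
    seed: int = 0


def simulate_doe(truth: SurfaceTruth, design: DesignMatrix,
                 response: str = "activity") -> pd.DataFrame:
    """Run table with responses y = surface(coded row) + N(0, noise_sd)."""
    if design.coded.shape[1] != truth.surface.k:
        raise ValueError("design and surface dimensionality differ")
    rng = np.random.default_rng(truth.seed)
    y = truth.surface.predict(design.coded)
    if truth.noise_sd > 0:
        y = y + rng.normal(0.0, truth.noise_sd, size=len(y))
    out = design.to_frame(actual=True)
    out[response] = y
    return out


def simulate_fermentation(truth: FermentationTruth) -> pd.DataFrame:
    """Time series for biomass and each Gompertz series, noised and floored at 0."""
    t = np.asarray(truth.times, dtype=float)
    rng = np.random.default_rng(truth.seed)
    out = pd.DataFrame({"time": t})

    def noised(curve):
        if truth.rel_noise_sd > 0:
            curve = curve * (1.0 + rng.normal(0.0, truth.rel_noise_sd, size=len(t)))
        return np.maximum(curve, 0.0)

    out["biomass"] = noised(logistic_curve(t, truth.biomass))
    for name, params in truth.series.items():
        out[name] = noised(gompertz_curve(t, params))
    return out


def _kinetic_preset(strain: str) -> dict:
    table = datasets.load_fixture("kinetic_parameters")
    if strain not in table:
        raise KeyError(f"unknown strain preset {strain!r}; available: {', '.join(table)}")
    return table[strain]


def surface_truth_preset(noise_sd: float = 0.0, seed: int = 0) -> SurfaceTruth:
    """The packaged coded-unit protease-activity surface as ground truth."""
    return SurfaceTruth(datasets.activity_surface(), noise_sd=noise_sd, seed=seed)


def fermentation_truth_preset(strain: str = "mutant", rel_noise_sd: float = 0.01,
                              seed: int = 0, times=None) -> FermentationTruth:
    """Fitted kinetic parameters of the packaged study strains as ground truth."""
    p = _kinetic_preset(strain)
    bio = p["biomass"]
    series = {name: GompertzParams(p[name]["Pmax"], p[name]["r_max"], p[name]["t_lag"])
              for name in ("total_protein", "activity", "substrate")}
    return FermentationTruth(
        biomass=LogisticParams(bio["X0"], bio["Xmax"], bio["mu_max"]),
        series=series,
        times=DEFAULT_TIMES.copy() if times is None else np.asarray(times, dtype=float),
        rel_noise_sd=rel_noise_sd, seed=seed)
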