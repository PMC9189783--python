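"""Packaged study tables from the source fermentation-optimization experiment.

The published experiment ships all of its quantitative results as printed
tables; they are stored here verbatim as small CSV/JSON files:

``strain_screening``
    Mutagenesis screening: clear-zone diameter, total protein (mg) and
    protease activity (U) per strain, with the printed percent improvement.
``ccrd_runs``
    The 50-run five-factor central composite design (actual factor levels)
    with experimental and model-predicted total protein (mg) and protease
    activity (U).  The printed matrix has 32 distinct factorial corners,
    10 axial points at coded distance 2 and 8 replicated centre runs.
``kinetic_parameters``
    Fitted logistic (biomass) and modified-Gompertz (protein, activity,
    substrate) parameters with goodness-of-fit, for mutant and wild type.
``atps_purification``
    Aqueous two-phase purification steps: total protein/activity and the
    derived specific activity, yield and purification fold per PEG size.
``activity_surface``
    The published 21-coefficient quadratic model of protease activity in
    coded units, with the factor definitions (low/high actual levels).

Values are stored digit-for-digit as printed, including the source's internal
inconsistencies; downstream code treats these tables as ground truth.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from ..doe import Factor, FactorSet
from ..rsm import SurfaceFit

__all__ = ["load_fixture", "ccrd_factors", "activity_surface", "FIXTURES"]

FIXTURES = ("strain_screening", "ccrd_runs", "kinetic_parameters",
            "atps_purification", "activity_surface")

#: columns of ccrd_runs holding actual factor levels, in design order
CCRD_FACTOR_COLUMNS = ["cpe", "csl", "casein", "mg", "mn"]


def _data(name: str):
    return resources.files(__package__) / "data" / name


def load_fixture(name: str):
    """Return a packaged table by fixture id.

    CSV-backed fixtures come back as a :class:`pandas.DataFrame`;
    ``kinetic_parameters`` as a nested dict keyed by strain and series;
    ``activity_surface`` as a :class:`~fermopt.rsm.SurfaceFit` in coded units.
    """
    if name == "strain_screening":
        return pd.read_csv(_data("strain_screening.csv"))
    if name == "ccrd_runs":
        return pd.read_csv(_data("ccrd_runs.csv"))
    if name == "atps_purification":
        return pd.read_csv(_data("atps_purification.csv"))
    if name == "kinetic_parameters":
        with _data("bioreactor_kinetics.json").open() as fh:
            return json.load(fh)
    if name == "activity_surface":
        return activity_surface()
    raise KeyError(f"unknown fixture {name!r}; available: {', '.join(FIXTURES)}")


def ccrd_factors() -> FactorSet:
    """Factor definitions (name, -1/+1 actual levels, units) of the 50-run design."""
    with _data("activity_surface_coded.json").open() as fh:
        spec = json.load(fh)
    return FactorSet([Factor(d["name"], d["low"], d["high"], d["units"])
                      for d in spec["factors"]])


def activity_surface() -> SurfaceFit:
    """The published coded-unit quadratic model of protease activity (U)."""
    with _data("activity_surface_coded.json").open() as fh:
        spec = json.load(fh)
    return SurfaceFit.from_coefficients(
        spec["intercept"], spec["linear"], spec["interaction"], spec["quadratic"],
        basis="coded", names=[d["name"] for d in spec["factors"]])
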