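"""Strain-improvement arithmetic and purification accounting.

Screening improvements are percent changes in activity relative to the parent
strain; aqueous two-phase purification steps are summarized by specific
activity (U/mg), activity yield relative to the crude extract (%) and
purification fold (ratio of specific activities); phase systems by volume
ratio and partition coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import pandas as pd

__all__ = ["PurificationStep", "PhaseSystem", "improvement_percent",
           "fold_change", "purification_report", "partition_stats",
           "screening_report"]


def improvement_percent(mutant_activity: float, parent_activity: float) -> float:
    """Percent improvement over the parent, rounded to 2 decimal places."""
    if parent_activity <= 0:
        raise ValueError("parent activity must be positive")
    return round(100.0 * (mutant_activity - parent_activity) / parent_activity, 2)


def fold_change(numerator: float, denominator: float) -> float:
    """Plain ratio, rounded to 2 decimal places."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(numerator / denominator, 2)


def screening_report(table: pd.DataFrame, *, activity_column: str = "activity_u",
                     parent_code: str = "parent") -> pd.DataFrame:
    """Recompute percent improvement and fold change for a screening table."""
    if parent_code not in set(table["code"]):
        raise ValueError(f"no parent record {parent_code!r} in table")
    parent = float(table.loc[table["code"] == parent_code, activity_column].iloc[0])
    out = table.copy()
    out["improvement_calc"] = [
        improvement_percent(a, parent) if code != parent_code else 0.0
        for code, a in zip(out["code"], out[activity_column])]
    out["fold_calc"] = [fold_change(a, parent) for a in out[activity_column]]
    return out


@dataclass(frozen=True)
class PurificationStep:
    label: str
    total_protein: float    # mg
    total_activity: float   # U

    def __post_init__(self) -> None:
        if self.total_protein <= 0 or self.total_activity <= 0:
            raise ValueError(f"step {self.label!r}: protein and activity must be positive")

    @property
    def specific_activity(self) -> float:
        return self.total_activity / self.total_protein


def purification_report(steps: list[PurificationStep],
                        crude: PurificationStep) -> pd.DataFrame:
    """Specific activity, activity yield (%) and purification fold per step.

    Yield is relative to the crude extract's total activity; fold is the
    ratio of specific activities (crude = 1.00 by construction).
    """
    rows = []
    for step in [crude] + [s for s in steps if s is not crude]:
        sa = step.specific_activity
        rows.append({
            "label": step.label,
            "total_protein": step.total_protein,
            "total_activity": step.total_activity,
            "specific_activity": sa,
            "yield_pct": 100.0 * step.total_activity / crude.total_activity,
            "fold": sa / crude.specific_activity,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PhaseSystem:
    """Top/bottom phase volumes (mL) and enzyme concentrations (U/mL)."""

    v_top: float
    v_bottom: float
    c_top: float
    c_bottom: float

    def __post_init__(self) -> None:
        if self.v_top <= 0 or self.v_bottom <= 0:
            raise ValueError("phase volumes must be positive")
        if self.c_top < 0 or self.c_bottom < 0:
            raise ValueError("concentrations must be non-negative")


def partition_stats(system: PhaseSystem) -> dict:
    """Volume ratio Vr = V_top/V_bottom and partition coefficient K = C_top/C_bottom.

    All-top partitioning (C_bottom = 0) is flagged one-sided with K = inf.
    """
    vr = system.v_top / system.v_bottom
    if system.c_bottom == 0:
        return {"volume_ratio": vr, "partition_coefficient": math.inf, "one_sided": True}
    return {"volume_ratio": vr,
            "partition_coefficient": system.c_top / system.c_bottom,
            "one_sided": False}
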