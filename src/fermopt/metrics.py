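"""Model-comparison metric suite for experimental vs predicted responses.

Seven metrics on the original response scale: coefficient of determination
(r2), mean squared error, root mean squared error, mean absolute error,
average absolute deviation (AAD, %), average relative error (ARE, %) and a
chi-squared error.  The chi-squared defaults to Pearson's form

    chi2 = sum (y - y')^2 / y'

which is the form consistent with the study tables this package reproduces;
the squared-relative variant sum ((y - y')/y')^2 is available as
``chi2_form="relative"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MetricReport", "compute_metrics", "compare_models"]

#: metrics where a larger value is better
_HIGHER_BETTER = {"r2"}
_METRICS = ("r2", "mse", "rmse", "mae", "aad", "are", "chi2")


@dataclass(frozen=True)
class MetricReport:
    r2: float
    mse: float
    rmse: float
    mae: float
    aad: float      # percent
    are: float      # percent
    chi2: float

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in _METRICS}


def compute_metrics(y_exp, y_pred, *, chi2_form: str = "pearson") -> MetricReport:
    """All seven comparison metrics between experimental and predicted values.

    Relative metrics (aad, are, chi2) divide by the predictions, so every
    prediction must be nonzero.
    """
    y = np.asarray(y_exp, dtype=float).ravel()
    yp = np.asarray(y_pred, dtype=float).ravel()
    if y.shape != yp.shape:
        raise ValueError("experimental and predicted vectors must have equal length")
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 observations")
    if np.any(yp == 0):
        raise ValueError("zero predicted value: relative metrics undefined")
    if chi2_form not in ("pearson", "relative"):
        raise ValueError(f"unknown chi2_form {chi2_form!r}")
    e = y - yp
    sse = float(e @ e)
    sst = float(((y - y.mean()) ** 2).sum())
    rel = e / yp
    chi2 = float(np.sum(e ** 2 / yp)) if chi2_form == "pearson" else float(np.sum(rel ** 2))
    return MetricReport(
        r2=1.0 - sse / sst,
        mse=sse / n,
        rmse=float(np.sqrt(sse / n)),
        mae=float(np.abs(e).mean()),
        aad=abs(float(rel.mean())) * 100.0,
        are=float(np.abs(rel).mean()) * 100.0,
        chi2=chi2,
    )


def compare_models(reports: dict[str, MetricReport]) -> dict:
    """Per-metric winners and a majority-vote verdict across models.

    Higher is better for r2, lower for every error metric.  Exact ties on a
    metric are recorded as ``None``; the overall verdict is the model winning
    the most metrics, or ``"tie"``.
    """
    if len(reports) < 2:
        raise ValueError("need at least two models to compare")
    winners: dict[str, str | None] = {}
    tally: dict[str, int] = {name: 0 for name in reports}
    for metric in _METRICS:
        values = {name: getattr(rep, metric) for name, rep in reports.items()}
        pick = max if metric in _HIGHER_BETTER else min
        best = pick(values.values())
        best_models = [name for name, v in values.items() if v == best]
        if len(best_models) == 1:
            winners[metric] = best_models[0]
            tally[best_models[0]] += 1
        else:
            winners[metric] = None
    top = max(tally.values())
    leaders = [name for name, c in tally.items() if c == top]
    return {
        "winners": winners,
        "wins": tally,
        "overall": leaders[0] if len(leaders) == 1 else "tie",
    }
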