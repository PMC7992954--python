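"""Growth-rate estimation and the fructolytic index.

The proliferative readout of a live-cell imaging experiment is percent
confluency over time; the growth rate of a well is the slope of an
ordinary least-squares line through that series (% confluency per hour).
The fructolytic index of a cell line compares its net growth in fructose
with its net growth in glucose, each relative to a sugar-free control:

    FI = (r_fructose - r_no_sugar) / (r_glucose - r_no_sugar)

An index near 0 means the line cannot use fructose as a growth substrate;
near 1 means it grows as well on fructose as on glucose.  Negative values
(fructose arm below the no-sugar control) are reported as-is.  The index
is undefined when the glucose arm does not outgrow the control, which is
guarded by an epsilon on the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, NonGlycolyticControlError, ParameterError

__all__ = [
    "ConfluencyTimeSeries",
    "GrowthRate",
    "FructolyticIndex",
    "IndexSummary",
    "fit_growth_rate",
    "fructolytic_index",
    "aggregate_index",
    "rank_cell_lines",
    "classify_fructolytic",
]

CONDITIONS = ("no_sugar", "glucose", "fructose")


@dataclass(frozen=True)
class ConfluencyTimeSeries:
    """Per-well percent-confluency measurements under one sugar condition."""

    times_h: np.ndarray
    confluency_pct: np.ndarray
    well: str = ""
    cell_line: str = ""
    condition: str = "no_sugar"
    concentration_mm: float = 0.0

    def __post_init__(self):
        t = np.asarray(self.times_h, dtype=float)
        c = np.asarray(self.confluency_pct, dtype=float)
        if t.size != c.size:
            raise ParameterError("times and confluency lengths differ")
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            raise ParameterError("times must be strictly increasing")
        if np.any((c < 0) | (c > 100)):
            raise ParameterError("confluency must lie in [0, 100]%")
        if self.condition not in CONDITIONS:
            raise ParameterError(f"unknown condition {self.condition!r}")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "confluency_pct", c)

    def __len__(self) -> int:
        return self.times_h.size


@dataclass(frozen=True)
class GrowthRate:
    """OLS line through a confluency series: slope in % confluency / hour."""

    slope: float
    intercept: float
    stderr: float  # residual standard error of the fit
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class FructolyticIndex:
    """Index value with its three component growth rates (% / hour)."""

    value: float
    rate_fructose: float
    rate_glucose: float
    rate_no_sugar: float
    n_replicates: int = 1


@dataclass(frozen=True)
class IndexSummary:
    """Replicate mean ± SEM of the fructolytic index for one cell line."""

    cell_line: str
    mean: float
    sem: float  # NaN with a single replicate
    n: int


def fit_growth_rate(
    series: ConfluencyTimeSeries,
    window_h: tuple[float, float] | None = None,
) -> GrowthRate:
    """Ordinary least-squares growth rate of a confluency series.

    ``window_h`` optionally restricts the regression to ``[t0, t1]``
    (inclusive), e.g. to exclude a lag phase; the default uses the full
    recorded time course.
    """
    t = series.times_h
    y = series.confluency_pct
    if window_h is not None:
        sel = (t >= window_h[0]) & (t <= window_h[1])
        t, y = t[sel], y[sel]
    if t.size < 3:
        raise InsufficientDataError("need at least 3 timepoints for a growth rate")
    if np.ptp(t) == 0:
        raise InsufficientDataError("zero time variance: degenerate design")
    res = stats.linregress(t, y)
    resid = y - (res.intercept + res.slope * t)
    dof = t.size - 2
    rse = float(np.sqrt(np.sum(resid**2) / dof)) if dof > 0 else np.nan
    return GrowthRate(
        slope=float(res.slope),
        intercept=float(res.intercept),
        stderr=rse,
        r_squared=float(res.rvalue**2),
        n_points=int(t.size),
    )


def fructolytic_index(
    rate_fru: GrowthRate,
    rate_glc: GrowthRate,
    rate_none: GrowthRate,
    epsilon: float = 0.05,
) -> FructolyticIndex:
    """(r_fru − r_none) / (r_glc − r_none), guarded by epsilon (%/h).

    Raises :class:`NonGlycolyticControlError` when the glucose arm fails
    to outgrow the no-sugar control by more than ``epsilon`` — the index
    is meaningless if the positive control did not grow.
    """
    denom = rate_glc.slope - rate_none.slope
    if denom <= epsilon:
        raise NonGlycolyticControlError(
            f"glucose arm grew only {denom:.3g} %/h over control (epsilon={epsilon})"
        )
    value = (rate_fru.slope - rate_none.slope) / denom
    return FructolyticIndex(
        value=float(value),
        rate_fructose=rate_fru.slope,
        rate_glucose=rate_glc.slope,
        rate_no_sugar=rate_none.slope,
    )


def aggregate_index(
    replicates: Sequence[FructolyticIndex], cell_line: str = ""
) -> IndexSummary:
    """Mean and SEM of the index over independent replicate experiments."""
    if len(replicates) < 1:
        raise InsufficientDataError("need at least one replicate")
    vals = np.array([r.value for r in replicates], dtype=float)
    mean = float(vals.mean())
    sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else float("nan")
    return IndexSummary(cell_line=cell_line, mean=mean, sem=sem, n=int(vals.size))


def rank_cell_lines(summaries: Sequence[IndexSummary]) -> list[IndexSummary]:
    """Ascending by mean index (least to most fructolytic); ties broken
    alphabetically by cell-line name."""
    if len(summaries) < 1:
        raise InsufficientDataError("need at least one cell line")
    return sorted(summaries, key=lambda s: (s.mean, s.cell_line))


def classify_fructolytic(summary: IndexSummary, threshold: float = 0.2) -> bool:
    """Call a line fructolytic when its mean index exceeds ``threshold``."""
    return summary.mean > threshold


def index_table(summaries: Sequence[IndexSummary]) -> pd.DataFrame:
    """Ranked summary table ready for CSV export."""
    ranked = rank_cell_lines(summaries)
    return pd.DataFrame(
        {
            "cell_line": [s.cell_line for s in ranked],
            "index_mean": [s.mean for s in ranked],
            "index_sem": [s.sem for s in ranked],
            "n_replicates": [s.n for s in ranked],
        }
    )
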