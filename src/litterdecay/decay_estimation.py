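"""Decay-rate estimation: per-bag instantaneous k and the multigroup fit.

Two estimators of the single-pool (Olson) decay constant are provided.

* ``instantaneous_k`` evaluates the closed form
  ``k = (ln remaining% - ln 100) / year_fraction`` for one bag.
* ``fit_multigroup`` extends the linearized model
  ``ln M_t = ln M_0 - k t`` to all 12 treatment cells at once: a single
  shared intercept plus one slope per cell, estimated by OLS, where the
  predictor column for cell *i* is ``t x indicator(cell i)``.  Intervals
  are t-based 95% bands; with flat priors they coincide numerically with
  the Bayesian credible intervals this design was analysed with.

Slopes and k values are stored with a negative sign for mass loss.
Physiological time (cumulative growing degree-days above a base
temperature) can replace calendar time as the predictor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data_model import ALL_CELLS, BagRecord, TreatmentCell

LN100 = math.log(100.0)


class EstimationError(ValueError):
    """The design cannot be estimated (rank deficiency, missing times)."""


@dataclass(frozen=True)
class InstantaneousK:
    """Per-bag decay rate with its provenance."""

    k: float
    record: BagRecord
    basis: Literal["whole-bag", "maple-in-mixed", "beech-in-mixed"] = "whole-bag"


@dataclass
class DecayFitResult:
    """Shared intercept plus per-cell slopes from the multigroup regression."""

    intercept: float
    intercept_interval: tuple[float, float]
    slopes: dict[TreatmentCell, float]
    slope_intervals: dict[TreatmentCell, tuple[float, float]]
    slope_se: dict[TreatmentCell, float]
    r_squared: float
    adj_r_squared: float
    nobs: int
    covariate_coefficients: dict[str, tuple[float, tuple[float, float]]] | None = None

    def slope_magnitude(self, cell: TreatmentCell) -> float:
        """Absolute decay rate, for ratio arithmetic."""
        return abs(self.slopes[cell])

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "cell": c.label,
            "slope": self.slopes[c],
            "ci_low": self.slope_intervals[c][0],
            "ci_high": self.slope_intervals[c][1],
            "se": self.slope_se[c],
        } for c in self.slopes]
        return pd.DataFrame(rows)


def instantaneous_k(percent_remaining: float, year_fraction: float) -> float:
    """Closed-form per-bag decay rate (year^-1), negative for any loss."""
    if percent_remaining <= 0:
        raise ValueError(
            "percent_remaining must be positive (total disappearance is "
            "outside the single-pool model)")
    if percent_remaining > 100:
        raise ValueError("percent_remaining cannot exceed 100")
    if year_fraction <= 0:
        raise ValueError("year_fraction must be positive")
    return (math.log(percent_remaining) - LN100) / year_fraction


def instantaneous_k_records(records: Sequence[BagRecord]) -> list[InstantaneousK]:
    """Whole-bag instantaneous k for every record."""
    return [InstantaneousK(instantaneous_k(r.percent_remaining, r.year_fraction), r)
            for r in records]


def _record_time(record: BagRecord,
                 time_basis: str,
                 gdd_by_plot: Mapping[str, pd.Series] | None) -> float:
    if time_basis == "year_fraction":
        return record.year_fraction
    if time_basis == "gdd":
        if gdd_by_plot is None:
            raise EstimationError("time_basis='gdd' requires a gdd_by_plot table")
        series = gdd_by_plot[record.plot]
        if record.removal_day not in series.index:
            raise EstimationError(
                f"no cumulative GDD at day {record.removal_day} for plot {record.plot}")
        return float(series.loc[record.removal_day])
    raise ValueError(f"unknown time basis {time_basis!r}")


def build_design_matrix(records: Sequence[BagRecord],
                        time_basis: str = "year_fraction",
                        gdd_by_plot: Mapping[str, pd.Series] | None = None,
                        ) -> tuple[np.ndarray, pd.DataFrame]:
    """Response vector ln(% remaining) and the shared-intercept design.

    Columns: ``intercept`` (ones), then one column per treatment cell in
    canonical order, holding elapsed time for records in that cell and 0
    elsewhere.  Cells with no records are dropped.
    """
    if len(records) == 0:
        raise EstimationError("cannot build a design matrix from zero records")
    y = np.array([math.log(r.percent_remaining) for r in records])
    cells_present = [c for c in ALL_CELLS if any(r.cell == c for r in records)]
    cols = {"intercept": np.ones(len(records))}
    for cell in cells_present:
        cols[cell.label] = np.array([
            _record_time(r, time_basis, gdd_by_plot) if r.cell == cell else 0.0
            for r in records])
    return y, pd.DataFrame(cols)


def fit_multigroup(records: Sequence[BagRecord],
                   time_basis: str = "year_fraction",
                   gdd_by_plot: Mapping[str, pd.Series] | None = None,
                   covariates: pd.DataFrame | None = None,
                   conf_level: float = 0.95) -> DecayFitResult:
    """OLS fit of the multigroup linearized decay model.

    ``covariates``, if given, is a plot-indexed DataFrame of numeric
    plot-level predictors joined onto each record and estimated jointly.
    Raises :class:`EstimationError` naming any cell observed at fewer than
    two distinct time points.
    """
    y, X = build_design_matrix(records, time_basis, gdd_by_plot)
    cells_present = [TreatmentCell.from_label(c) for c in X.columns[1:]]
    for cell in cells_present:
        times = {_record_time(r, time_basis, gdd_by_plot)
                 for r in records if r.cell == cell}
        if len(times) < 2:
            raise EstimationError(
                f"cell {cell.label} is observed at {len(times)} distinct time "
                f"point(s); at least 2 are required")
    if covariates is not None:
        for name in covariates.columns:
            X[name] = [float(covariates.loc[r.plot, name]) for r in records]
    model = sm.OLS(y, X)
    fit = model.fit()
    ci = fit.conf_int(alpha=1 - conf_level)
    slopes = {c: float(fit.params[c.label]) for c in cells_present}
    intervals = {c: (float(ci.loc[c.label, 0]), float(ci.loc[c.label, 1]))
                 for c in cells_present}
    ses = {c: float(fit.bse[c.label]) for c in cells_present}
    covariate_coefficients = None
    if covariates is not None:
        covariate_coefficients = {
            name: (float(fit.params[name]),
                   (float(ci.loc[name, 0]), float(ci.loc[name, 1])))
            for name in covariates.columns}
    return DecayFitResult(
        intercept=float(fit.params["intercept"]),
        intercept_interval=(float(ci.loc["intercept", 0]),
                            float(ci.loc["intercept", 1])),
        slopes=slopes,
        slope_intervals=intervals,
        slope_se=ses,
        r_squared=float(fit.rsquared),
        adj_r_squared=float(fit.rsquared_adj),
        nobs=int(fit.nobs),
        covariate_coefficients=covariate_coefficients,
    )


def accumulate_gdd(temperature: pd.DataFrame, base: float = 5.0) -> pd.Series:
    """Cumulative growing degree-days from a sub-daily temperature log.

    ``temperature`` needs ``timestamp`` and ``temp_c`` columns.  Each day
    contributes ``max(0, daily mean - base)``; the running sum is returned
    indexed by day number (1-based from the first logged day).  Days with
    internal gaps larger than 1.5x the median logging interval are dropped
    with a warning.
    """
    if temperature.empty:
        raise ValueError("temperature log is empty")
    frame = temperature.copy()
    frame["timestamp"] = pd.to_datetime(frame["timestamp"])
    frame = frame.sort_values("timestamp")
    interval = frame["timestamp"].diff().dropna()
    median_interval = interval.median() if len(interval) else pd.Timedelta(0)
    first_day = frame["timestamp"].dt.normalize().min()
    contributions = {}
    for date, group in frame.groupby(frame["timestamp"].dt.normalize()):
        gaps = group["timestamp"].diff().dropna()
        if len(gaps) and median_interval > pd.Timedelta(0) \
                and gaps.max() > 1.5 * median_interval:
            warnings.warn(f"temperature log gap on {date.date()}; day excluded")
            continue
        day_number = int((date - first_day).days) + 1
        contributions[day_number] = max(0.0, group["temp_c"].mean() - base)
    series = pd.Series(contributions, name="gdd").sort_index().cumsum()
    series.index.name = "day"
    return series
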