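"""Signal conditioning: smoothing, standard-score normalization, the foot
pressure ratio, and rate reconciliation.

All operations are pure: they take a :class:`~skimu.types.TimeSeries` (or a
pair of insole streams) and return a new series.  Array-oriented sklearn
transformers (:class:`MovingAverage`, :class:`StandardScore`) wrap the same
computations for use in pipelines on column-stacked signals.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .types import InsoleStream, TimeSeries

#: Two-foot total force below this is treated as "not on the snow" and the
#: pressure ratio sample is flagged invalid (NaN).
DEFAULT_FORCE_FLOOR = 1e-6


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    # Centered window; at the ends the window shrinks to the available
    # samples, so output length equals input length.
    return (
        pd.Series(values)
        .rolling(window=window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def moving_average(series: TimeSeries, window: int = 5) -> TimeSeries:
    """Centered moving average with truncated edge windows.

    Parameters
    ----------
    series : TimeSeries
    window : int
        Odd window length; the field-standard five-point smoother by default.

    Returns
    -------
    TimeSeries of the same length.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    if window > len(series):
        raise ValueError(f"window {window} exceeds series length {len(series)}")
    return series.with_values(_moving_average(series.values, window))


def zscore(series: TimeSeries) -> TimeSeries:
    """Standard-score normalization: (x - mean) / sd with the n-1 denominator.

    Raises
    ------
    ValueError
        If the series is shorter than 2 samples or constant (sd = 0), naming
        the offending trace.
    """
    if len(series) < 2:
        raise ValueError(f"zscore needs >= 2 samples, trace {series.label!r} has {len(series)}")
    sd = float(np.std(series.values, ddof=1))
    if sd == 0.0:
        raise ValueError(f"zscore undefined for constant trace {series.label!r}")
    return series.with_values((series.values - series.values.mean()) / sd)


def foot_pressure_ratio(
    left: InsoleStream,
    right: InsoleStream,
    force_floor: float = DEFAULT_FORCE_FLOOR,
) -> TimeSeries:
    """Signed left/right loading contrast r = (F_L - F_R) / (F_L + F_R).

    F_L and F_R are the per-sample sums over each insole's 13 cells.  The
    ratio is positive when the left foot carries more load, which is the
    outer-foot situation of a right turn; with the roll convention (positive
    = leaning right) the ratio therefore co-varies positively with roll.

    Samples whose two-foot total falls below ``force_floor`` are flagged
    invalid as NaN (e.g., airborne phases).  A stream with zero total force
    throughout is rejected.
    """
    if left.pressures.shape[0] != right.pressures.shape[0]:
        raise ValueError("left and right insole streams must have equal length")
    if left.rate_hz != right.rate_hz:
        raise ValueError("left and right insole streams must share a sampling rate")
    f_l = left.total_force
    f_r = right.total_force
    total = f_l + f_r
    if np.all(total <= force_floor):
        raise ValueError("total foot force is zero over the whole stream")
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > force_floor, (f_l - f_r) / total, np.nan)
    return TimeSeries(ratio, rate_hz=left.rate_hz, t0=left.t0, label="foot_pressure_ratio")


def resample_to(series: TimeSeries, target_rate_hz: float) -> TimeSeries:
    """Linear interpolation onto a uniform grid at ``target_rate_hz``.

    The output grid spans the input's own time span (no extrapolation).
    Needed to put the 50 Hz pressure ratio and 100 Hz roll traces on one grid
    before correlating them.
    """
    if not target_rate_hz > 0:
        raise ValueError("target_rate_hz must be > 0")
    if series.rate_hz == target_rate_hz:
        return series
    t_in = series.times
    n_out = int(np.floor(series.duration_s * target_rate_hz)) + 1
    if n_out < 1:
        raise ValueError("target span is empty at the requested rate")
    t_out = series.t0 + np.arange(n_out) / target_rate_hz
    values = np.interp(t_out, t_in, series.values)
    return TimeSeries(values, rate_hz=target_rate_hz, t0=series.t0, label=series.label)


class MovingAverage(TransformerMixin, BaseEstimator):
    """Column-wise centered moving average with truncated edge windows.

    sklearn-compatible transformer over a 2-D array of column-stacked
    signals; ``transform`` preserves shape.
    """

    def __init__(self, window: int = 5):
        self.window = window

    def fit(self, X, y=None):
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 1, got {self.window}")
        X = check_array(X)
        if self.window > X.shape[0]:
            raise ValueError(f"window {self.window} exceeds signal length {X.shape[0]}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        return np.column_stack([_moving_average(X[:, j], self.window) for j in range(X.shape[1])])


class StandardScore(TransformerMixin, BaseEstimator):
    """Column-wise standard-score normalization with the n-1 denominator.

    Unlike ``sklearn.preprocessing.StandardScaler`` this uses the sample
    (ddof=1) standard deviation, matching the correlation denominator used
    downstream, and rejects constant columns instead of passing them through.
    """

    def fit(self, X, y=None):
        X = check_array(X)
        if X.shape[0] < 2:
            raise ValueError("StandardScore needs >= 2 samples")
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        if np.any(self.scale_ == 0):
            bad = int(np.flatnonzero(self.scale_ == 0)[0])
            raise ValueError(f"column {bad} is constant; standard score undefined")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        return (X - self.mean_) / self.scale_
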