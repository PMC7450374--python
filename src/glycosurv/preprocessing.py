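"""Resampling, imputation, smoothing and the insulin-to-carbohydrate ratio.

The preprocessing chain turns a raw :class:`~glycosurv.data_model.EventLog`
into uniform hourly or daily bins (glucose averaged, insulin and carbs
summed), fills missing glucose bins with a cubic spline, smooths every
channel with a *trailing* moving average (default window 48 hours), and only
then forms the bolus-to-carbohydrate ratio.  Computing the ratio after
smoothing avoids the division blow-ups that raw hourly bins produce, where
most bins contain no carbohydrate entry at all.

Bins are half-open ``[start, start + width)`` and events are assigned by
timestamp truncation, so a 23:59 dose stays in its calendar day.  Bins with
no insulin or carbohydrate entries hold true zeros (the logs are event
streams: absence of an entry means no intake), whereas glucose bins with no
sample are missing and eligible for imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .data_model import EventLog, InsulinKind

__all__ = [
    "BinnedSeries",
    "SmoothedSeries",
    "InsufficientDataError",
    "resample",
    "impute_bg",
    "moving_average",
    "ratio_series",
    "preprocess",
]

HOUR = pd.Timedelta(hours=1)
DAY = pd.Timedelta(days=1)

BIN_COLUMNS = ["bg_mean", "bolus_sum", "basal_sum", "carb_sum", "n_bg", "imputed"]


class InsufficientDataError(ValueError):
    pass


@dataclass
class BinnedSeries:
    """Uniformly resampled series; index is the bin start instant."""

    bin_width: pd.Timedelta
    frame: pd.DataFrame  # columns: bg_mean, bolus_sum, basal_sum, carb_sum, n_bg, imputed

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def bins(self) -> pd.DatetimeIndex:
        return self.frame.index

    def to_csv(self, path) -> None:
        self.frame.rename_axis("bin_start").to_csv(path)


@dataclass
class SmoothedSeries:
    """Trailing moving-average series with derived insulin-to-carb ratios.

    ``ratio_bolus``/``ratio_basal`` are NaN exactly where the smoothed
    carbohydrate level is zero; defined values are always finite.
    """

    window: pd.Timedelta
    bin_width: pd.Timedelta
    frame: pd.DataFrame  # columns: bg, bolus, basal, carbs, ratio_bolus, ratio_basal

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def bins(self) -> pd.DatetimeIndex:
        return self.frame.index

    @property
    def ratio_defined(self) -> pd.Series:
        return self.frame["ratio_bolus"].notna()

    def to_csv(self, path) -> None:
        self.frame.rename_axis("bin_start").to_csv(path)


def _bin_index(log: EventLog, bin_width: pd.Timedelta) -> pd.DatetimeIndex:
    if log.span is None:
        return pd.DatetimeIndex([])
    start = log.span[0]
    end = log.span[1] + DAY  # exclusive
    return pd.date_range(start, end, freq=bin_width, inclusive="left")


def resample(log: EventLog, bin_width: pd.Timedelta = HOUR) -> BinnedSeries:
    """Assign every record to its time bin; average glucose, sum insulin/carbs."""
    bin_width = pd.Timedelta(bin_width)
    if bin_width not in (HOUR, DAY):
        raise ValueError(f"bin_width must be 1 hour or 1 day, got {bin_width}")
    index = _bin_index(log, bin_width)
    frame = pd.DataFrame(
        {
            "bg_mean": np.nan,
            "bolus_sum": 0.0,
            "basal_sum": 0.0,
            "carb_sum": 0.0,
            "n_bg": 0,
            "imputed": False,
        },
        index=index,
    )
    if not len(index):
        return BinnedSeries(bin_width, frame)

    def key(ts: pd.Timestamp) -> pd.Timestamp:
        return ts.floor(bin_width)

    if log.glucose:
        g = pd.DataFrame(
            {"bin": [key(r.timestamp) for r in log.glucose], "value": [r.value for r in log.glucose]}
        )
        grouped = g.groupby("bin")["value"]
        frame.loc[grouped.mean().index, "bg_mean"] = grouped.mean()
        frame.loc[grouped.count().index, "n_bg"] = grouped.count()
    for kind, col in ((InsulinKind.BOLUS, "bolus_sum"), (InsulinKind.BASAL, "basal_sum")):
        doses = [r for r in log.insulin if r.kind == kind]
        if doses:
            d = pd.DataFrame({"bin": [key(r.timestamp) for r in doses], "units": [r.units for r in doses]})
            s = d.groupby("bin")["units"].sum()
            frame.loc[s.index, col] = s
    if log.carbs:
        c = pd.DataFrame(
            {"bin": [key(r.timestamp) for r in log.carbs], "grams": [r.grams for r in log.carbs]}
        )
        s = c.groupby("bin")["grams"].sum()
        frame.loc[s.index, "carb_sum"] = s
    frame["n_bg"] = frame["n_bg"].astype(int)
    return BinnedSeries(bin_width, frame)


def impute_bg(series: BinnedSeries) -> BinnedSeries:
    """Fill missing glucose bins with a natural cubic spline over bin index.

    Interior gaps are spline-interpolated; leading/trailing missing bins are
    extended with the nearest known value.  Imputed bins are flagged; the
    input is not modified.
    """
    frame = series.frame.copy()
    bg = frame["bg_mean"].to_numpy(dtype=float)
    known = np.flatnonzero(~np.isnan(bg))
    missing = np.flatnonzero(np.isnan(bg))
    if len(missing) == 0:
        return BinnedSeries(series.bin_width, frame)
    if len(known) < 4:
        raise InsufficientDataError(
            f"cubic-spline imputation needs >= 4 known glucose bins, have {len(known)}; "
            "use daily bins or supply more data"
        )
    spline = CubicSpline(known, bg[known], bc_type="natural")
    interior = missing[(missing > known[0]) & (missing < known[-1])]
    bg[interior] = spline(interior)
    bg[missing[missing < known[0]]] = bg[known[0]]
    bg[missing[missing > known[-1]]] = bg[known[-1]]
    frame["bg_mean"] = bg
    frame.loc[frame.index[missing], "imputed"] = True
    return BinnedSeries(series.bin_width, frame)


def moving_average(series: BinnedSeries, window: pd.Timedelta = pd.Timedelta(hours=48)) -> SmoothedSeries:
    """Trailing moving average of all channels over ``window``.

    Each output bin ``t`` is the mean of bins ``max(0, t-N+1)..t`` where
    ``N = window / bin_width``; windows at the head of the series are
    shortened so the output has the same length as the input.  The window
    uses only current and past bins — smoothing delays, never anticipates.
    """
    window = pd.Timedelta(window)
    if window < series.bin_width:
        raise ValueError(f"window {window} smaller than bin width {series.bin_width}")
    n = window / series.bin_width
    if n != int(n):
        raise ValueError(f"window {window} is not an integer multiple of bin width {series.bin_width}")
    n = int(n)
    rolled = series.frame[["bg_mean", "bolus_sum", "basal_sum", "carb_sum"]].rolling(
        n, min_periods=1
    ).mean()
    frame = rolled.rename(
        columns={"bg_mean": "bg", "bolus_sum": "bolus", "basal_sum": "basal", "carb_sum": "carbs"}
    )
    smoothed = SmoothedSeries(window=window, bin_width=series.bin_width, frame=frame)
    return ratio_series(smoothed)


def ratio_series(smoothed: SmoothedSeries) -> SmoothedSeries:
    """Derive bolus- and basal-to-carbohydrate ratios from smoothed channels.

    The ratio is undefined (NaN) wherever smoothed carbs are zero; defined
    values are guaranteed finite.
    """
    frame = smoothed.frame.copy()
    carbs = frame["carbs"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_b = np.where(carbs > 0, frame["bolus"].to_numpy(dtype=float) / carbs, np.nan)
        ratio_a = np.where(carbs > 0, frame["basal"].to_numpy(dtype=float) / carbs, np.nan)
    frame["ratio_bolus"] = ratio_b
    frame["ratio_basal"] = ratio_a
    return replace(smoothed, frame=frame)


def preprocess(
    log: EventLog,
    bin_width: pd.Timedelta = DAY,
    window: pd.Timedelta = pd.Timedelta(hours=48),
    impute: bool | None = None,
) -> tuple[BinnedSeries, SmoothedSeries]:
    """Full chain: resample -> (impute if hourly) -> moving average -> ratios."""
    binned = resample(log, bin_width)
    if impute is None:
        impute = pd.Timedelta(bin_width) == HOUR
    if impute and binned.frame["bg_mean"].isna().any():
        binned = impute_bg(binned)
    return binned, moving_average(binned, window)
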