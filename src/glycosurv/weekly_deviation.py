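"""Weekly infection-vs-reference deviation statistics.

For each self-reported infection episode, three 7-day windows are compared
on raw daily aggregates: the *preinfection week* (7 days ending the day
before onset), the *infection week* (7 days from onset) and the
*postinfection week* (the 7 days after that).  Per-week means and sample
standard deviations are computed over daily values — daily mean blood
glucose, daily bolus/basal sums, daily carbohydrate totals — and the
infection week is expressed as a percentage increase (glucose, insulin,
ratio) or reduction (carbohydrate) against each flanking week.

Across cases, per-case percentages are combined by an unweighted arithmetic
mean.  The characteristic infection signature is a simultaneous rise in
glucose *and* insulin with reduced carbohydrate intake — the opposite of
what those controllable inputs produce on ordinary days.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_model import EventLog, InfectionEvent
from .preprocessing import DAY, BinnedSeries, InsufficientDataError, SmoothedSeries, resample

__all__ = [
    "Direction",
    "Parameter",
    "WeekSummary",
    "DeviationReport",
    "AggregateDeviation",
    "summarize_week",
    "percent_change",
    "case_report",
    "reports_from_summaries",
    "ratio_shift",
    "aggregate_cases",
    "flag_discrepancies",
]


class Direction(str, enum.Enum):
    INCREASE = "increase"
    REDUCTION = "reduction"


class Parameter(str, enum.Enum):
    BG = "bg"
    BOLUS = "bolus"
    BASAL = "basal"
    TOTAL_INSULIN = "total_insulin"
    CARBS = "carbs"
    RATIO = "ratio"


#: Reporting direction per parameter: glucose/insulin/ratio deviations are
#: reported as increases ("over" the reference), carbohydrate as a reduction
#: ("below" the reference).
PARAMETER_DIRECTION = {
    Parameter.BG: Direction.INCREASE,
    Parameter.BOLUS: Direction.INCREASE,
    Parameter.BASAL: Direction.INCREASE,
    Parameter.TOTAL_INSULIN: Direction.INCREASE,
    Parameter.CARBS: Direction.REDUCTION,
    Parameter.RATIO: Direction.INCREASE,
}


@dataclass(frozen=True)
class WeekSummary:
    """Mean and sample SD (n-1) of daily values over one 7-day window.

    Carbohydrate and basal fields are ``None`` when that stream was not
    recorded for the case.
    """

    window_start: pd.Timestamp | None
    bg_mean: float
    bg_sd: float
    bolus_mean: float
    bolus_sd: float
    carb_mean: float | None = None
    carb_sd: float | None = None
    basal_mean: float | None = None
    basal_sd: float | None = None
    total_insulin_mean: float | None = None
    total_insulin_sd: float | None = None
    n_days: int = 7

    def __post_init__(self):
        for name in ("bg_sd", "bolus_sd", "carb_sd", "basal_sd", "total_insulin_sd"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_days > 7:
            raise ValueError("a week has at most 7 days")


@dataclass(frozen=True)
class DeviationReport:
    """Infection-week deviation of one parameter against both flanking weeks."""

    case_id: str
    parameter: Parameter
    pct_vs_pre: float
    pct_vs_post: float
    direction: Direction

    def rounded(self, ndigits: int = 2) -> "DeviationReport":
        return DeviationReport(
            self.case_id,
            self.parameter,
            round(self.pct_vs_pre, ndigits),
            round(self.pct_vs_post, ndigits),
            self.direction,
        )


@dataclass(frozen=True)
class AggregateDeviation:
    parameter: Parameter
    mean_pct_vs_pre: float
    mean_pct_vs_post: float
    n_cases: int


def percent_change(infection_value: float, reference_value: float, direction: Direction) -> float:
    """Percentage deviation of the infection week from a reference week.

    ``increase`` is 100*(infection - reference)/reference; ``reduction`` is
    100*(reference - infection)/reference.  The unrounded value is returned;
    reporting rounds to two decimals.
    """
    if reference_value <= 0:
        raise ValueError(f"reference value must be > 0, got {reference_value}")
    direction = Direction(direction)
    if direction is Direction.INCREASE:
        return 100.0 * (infection_value - reference_value) / reference_value
    return 100.0 * (reference_value - infection_value) / reference_value


def _week_frame(series: BinnedSeries, window_start: pd.Timestamp) -> pd.DataFrame:
    if series.bin_width != DAY:
        raise ValueError("weekly summaries are computed on daily bins")
    window_start = pd.Timestamp(window_start).normalize()
    window_end = window_start + pd.Timedelta(days=7)
    return series.frame.loc[(series.frame.index >= window_start) & (series.frame.index < window_end)]


def summarize_week(series: BinnedSeries, window_start: pd.Timestamp) -> WeekSummary:
    """Mean/SD of the week's daily BG means and daily insulin/carb sums."""
    week = _week_frame(series, window_start)
    covered = week["bg_mean"].notna()
    if int(covered.sum()) < 4:
        raise InsufficientDataError(
            f"week starting {pd.Timestamp(window_start).date()} covers only "
            f"{int(covered.sum())} of 7 days"
        )
    bg = week.loc[covered, "bg_mean"]

    def stats(values: pd.Series) -> tuple[float, float]:
        return float(values.mean()), float(values.std(ddof=1))

    bg_mean, bg_sd = stats(bg)
    bolus_mean, bolus_sd = stats(week["bolus_sum"])
    carb_mean, carb_sd = stats(week["carb_sum"])
    kwargs: dict = {}
    if (week["basal_sum"] > 0).any():
        kwargs["basal_mean"], kwargs["basal_sd"] = stats(week["basal_sum"])
        total = week["bolus_sum"] + week["basal_sum"]
        kwargs["total_insulin_mean"], kwargs["total_insulin_sd"] = stats(total)
    return WeekSummary(
        window_start=pd.Timestamp(window_start).normalize(),
        bg_mean=bg_mean,
        bg_sd=bg_sd,
        bolus_mean=bolus_mean,
        bolus_sd=bolus_sd,
        carb_mean=carb_mean,
        carb_sd=carb_sd,
        n_days=int(covered.sum()),
        **kwargs,
    )


def reports_from_summaries(
    case_id: str,
    pre: WeekSummary,
    infection: WeekSummary,
    post: WeekSummary,
) -> list[DeviationReport]:
    """Deviation reports from three week summaries (pre, infection, post)."""
    reports: list[DeviationReport] = []

    def add(parameter: Parameter, attr: str) -> None:
        values = [getattr(w, attr) for w in (infection, pre, post)]
        if any(v is None for v in values):
            return
        direction = PARAMETER_DIRECTION[parameter]
        reports.append(
            DeviationReport(
                case_id=case_id,
                parameter=parameter,
                pct_vs_pre=percent_change(values[0], values[1], direction),
                pct_vs_post=percent_change(values[0], values[2], direction),
                direction=direction,
            )
        )

    add(Parameter.BG, "bg_mean")
    add(Parameter.BOLUS, "bolus_mean")
    add(Parameter.CARBS, "carb_mean")
    add(Parameter.BASAL, "basal_mean")
    add(Parameter.TOTAL_INSULIN, "total_insulin_mean")
    return reports


def case_report(
    log: EventLog,
    infection: InfectionEvent,
    series: BinnedSeries | None = None,
    week_offset: int = 0,
) -> list[DeviationReport]:
    """Deviation reports for one infection episode of a patient-year.

    The infection week starts on the self-reported onset date (shift with
    ``week_offset`` days if a different anchoring is wanted); the flanking
    weeks are the 7 days before and the 7 days after the infection week.
    """
    anchor = infection.onset + pd.Timedelta(days=week_offset)
    if series is None:
        series = resample(log, DAY)
    lo, hi = series.bins.min(), series.bins.max()
    if anchor - pd.Timedelta(days=7) < lo or anchor + pd.Timedelta(days=14) > hi + DAY:
        raise InsufficientDataError(
            f"log does not span [onset - 7 d, onset + 14 d] around {anchor.date()}"
        )
    pre = summarize_week(series, anchor - pd.Timedelta(days=7))
    inf = summarize_week(series, anchor)
    post = summarize_week(series, anchor + pd.Timedelta(days=7))
    case_id = f"{log.patient_id}:{anchor.date()}"
    return reports_from_summaries(case_id, pre, inf, post)


def ratio_shift(
    smoothed: SmoothedSeries,
    infection: InfectionEvent,
    infections: Sequence[InfectionEvent] | None = None,
) -> float:
    """Infection-week rise of the bolus-to-carb ratio above the operating point.

    The normal operating point is the mean smoothed daily ratio over all
    non-infection days of the same patient-year (every reported episode is
    excluded, not only the one under analysis); the return value is
    100 * (infection-week mean ratio - operating point) / operating point.
    """
    if smoothed.bin_width != DAY:
        raise ValueError("ratio_shift expects a daily smoothed series")
    if infections is None:
        infections = [infection]
    ratio = smoothed.frame["ratio_bolus"]
    days = smoothed.bins.normalize()
    week_mask = (days >= infection.onset) & (days < infection.onset + pd.Timedelta(days=7))
    week_ratio = ratio[week_mask].dropna()
    if len(week_ratio) < 4:
        raise InsufficientDataError("smoothed ratio defined on fewer than 4 infection-week days")
    excluded = np.zeros(len(days), dtype=bool)
    for ep in infections:
        excluded |= np.asarray((days >= ep.onset) & (days < ep.end))
    baseline = ratio[~excluded].dropna()
    if not len(baseline):
        raise InsufficientDataError("no non-infection days to define the operating point")
    operating_point = float(baseline.mean())
    return percent_change(float(week_ratio.mean()), operating_point, Direction.INCREASE)


def aggregate_cases(reports: Iterable[DeviationReport]) -> list[AggregateDeviation]:
    """Arithmetic mean of per-case percentages, per parameter and reference side."""
    reports = list(reports)
    if not reports:
        raise ValueError("no deviation reports to aggregate")
    out: list[AggregateDeviation] = []
    for parameter in Parameter:
        subset = [r for r in reports if r.parameter == parameter]
        if not subset:
            continue
        out.append(
            AggregateDeviation(
                parameter=parameter,
                mean_pct_vs_pre=float(np.mean([r.pct_vs_pre for r in subset])),
                mean_pct_vs_post=float(np.mean([r.pct_vs_post for r in subset])),
                n_cases=len(subset),
            )
        )
    return out


def flag_discrepancies(
    computed: Iterable[DeviationReport],
    printed: dict[tuple[str, Parameter], tuple[float | None, float | None]],
    tol: float = 0.02,
) -> list[tuple[str, Parameter, str, float, float]]:
    """Cross-check computed percentages against published per-case figures.

    ``printed`` maps (case_id, parameter) to (pct_vs_pre, pct_vs_post) as
    published (``None`` to skip a side).  Returns one tuple
    (case_id, parameter, side, computed, printed) per disagreement beyond
    ``tol`` percentage points — useful because published analyses sometimes
    carry internal inconsistencies that should be surfaced, not reproduced.
    """
    flags = []
    for r in computed:
        key = (r.case_id, r.parameter)
        if key not in printed:
            continue
        for side, value in zip(("pre", "post"), printed[key]):
            if value is None:
                continue
            got = r.pct_vs_pre if side == "pre" else r.pct_vs_post
            if abs(got - value) > tol:
                flags.append((r.case_id, r.parameter, side, got, value))
    return flags
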