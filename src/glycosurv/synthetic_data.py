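"""Seeded generator of realistic type 1 diabetes patient-years.

Real long-horizon self-management logs with annotated infection episodes are
essentially impossible to obtain publicly, so every pipeline stage here is
exercised against simulated patient-years with known ground truth.  The
generator couples a simple behavioural layer (meals, carbohydrate counting,
bolus dosing, corrections) to a one-compartment hourly glucose balance

    BG[t+1] = BG[t] + k_c*CH[t] - phi(t)*k_i*IN[t] + EGP(t)
                    - k_d*(BG[t] - bg_target) + process noise

where ``phi`` is the insulin sensitivity factor and ``EGP`` an extra hepatic
glucose production term driven by counterregulatory stress hormones.  During
an infection episode ``phi`` falls, ``EGP`` rises and appetite drops, each
following a piecewise-linear intensity ramp that peaks mid-episode.  The
simulated patient *chases* the increased insulin need — higher meal ratios
plus correction boluses — but only partially (``compensation`` < 1), which
reproduces the empirical infection signature: elevated glucose despite more
insulin and fewer carbohydrates, and a bolus-to-carb ratio that climbs from
the normal 0.05-0.2 U/g band toward 0.3-0.6 at mid-episode.

This is an aggregate behavioural model, not a physiological one: insulin
action and meal absorption are instantaneous at the hourly step, and
physical activity is fixed at zero (the emulated logs carry no activity
stream).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import (
    CarbIntake,
    EventLog,
    GlucoseSample,
    GlucoseSource,
    InfectionEvent,
    InsulinDose,
    InsulinKind,
)
from .weekly_deviation import WeekSummary

__all__ = [
    "EpisodeConfig",
    "SimulationConfig",
    "GroundTruth",
    "generate_patient_year",
    "reference_cases",
    "REPORTED_CHANGES",
    "REPORTED_RATIO_INCREASES",
]

# Glucose-balance constants, shared by the simulated physiology and the
# simulated patient's dosing arithmetic.  k_c: mg/dL rise per gram of
# carbohydrate; k_i: mg/dL drop per insulin unit at full sensitivity
# (tied to k_c so that the steady-state bolus-to-carb ratio equals the
# configured operating point); k_d: fractional hourly relaxation toward the
# glycemic set point (insulin-independent disposal plus basal coverage).
K_C = 3.0  # mg/dL per g
K_D = 0.15  # 1/h
PROCESS_SD = 3.0  # mg/dL per hour, unexplained physiological drift
CORRECTION_THRESHOLD = 20.0  # mg/dL above target before a correction bolus
DOSE_CV = 0.10  # carb-counting / dosing noise, coefficient of variation
SIM_START = pd.Timestamp("2021-01-04")  # a Monday; arbitrary but fixed


@dataclass(frozen=True)
class EpisodeConfig:
    """One infection episode and its severity profile.

    ``ramp`` gives (episode fraction, intensity) breakpoints of the
    piecewise-linear severity profile: effects switch on at onset, rise to
    the mid-episode peak, and decay toward recovery.  ``sensitivity_drop``,
    ``egp_boost`` and ``appetite_drop`` are the peak (intensity = 1) effect
    sizes; ``compensation`` is the fraction of the *extra* insulin need the
    patient actually delivers.
    """

    onset_day: int
    duration_days: int = 10
    sensitivity_drop: float = 0.5
    egp_boost: float = 4.5  # mg/dL per hour at peak
    appetite_drop: float = 0.28
    compensation: float = 0.85
    label: str = "flu"
    ramp: tuple[tuple[float, float], ...] = ((0.0, 0.7), (0.5, 1.0), (1.0, 0.35))

    def __post_init__(self):
        if self.duration_days < 1:
            raise ValueError("episode duration must be >= 1 day")
        for name in ("sensitivity_drop", "appetite_drop", "compensation"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.egp_boost < 0:
            raise ValueError("egp_boost must be >= 0")

    def intensity(self, day_fraction: float) -> float:
        """Severity in [0, 1] at ``day_fraction`` of the episode (0 = onset)."""
        if not (0.0 <= day_fraction < 1.0):
            return 0.0
        xs = [p[0] for p in self.ramp]
        ys = [p[1] for p in self.ramp]
        return float(np.interp(day_fraction, xs, ys))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated patient-year."""

    days: int = 365
    seed: int = 0
    meals_per_day: tuple[int, int] = (3, 5)
    daily_carbs_mean: float = 200.0  # g/day
    daily_carbs_sd: float = 40.0
    baseline_ratio: float = 0.15  # U/g, normal operating point in [0.05, 0.2]
    basal_daily: float = 19.0  # U/day; 0 emulates subjects without basal logging
    bg_target: float = 125.0  # mg/dL
    noise_sd: float = 15.0  # CGM measurement noise, mg/dL
    cgm_interval_min: int = 60
    missing_bg_rate: float = 0.05
    episodes: tuple[EpisodeConfig, ...] = ()

    def __post_init__(self):
        if not (0.05 <= self.baseline_ratio <= 0.2):
            raise ValueError("baseline_ratio must lie in the normal band [0.05, 0.2]")
        for name in ("daily_carbs_sd", "noise_sd", "missing_bg_rate", "basal_daily"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        episodes = sorted(self.episodes, key=lambda e: e.onset_day)
        for ep in episodes:
            if ep.onset_day < 0 or ep.onset_day + ep.duration_days > self.days:
                raise ValueError(f"episode at day {ep.onset_day} falls outside the simulated span")
        for a, b in zip(episodes, episodes[1:]):
            if b.onset_day < a.onset_day + a.duration_days:
                raise ValueError(f"episodes at days {a.onset_day} and {b.onset_day} overlap")

    def with_default_episode(self, onset_day: int = 180, **kwargs) -> "SimulationConfig":
        return replace(self, episodes=(EpisodeConfig(onset_day=onset_day, **kwargs),))


@dataclass
class GroundTruth:
    """Per-day truth of the simulation: infection state and latent effects."""

    frame: pd.DataFrame  # index: day; columns: infected, phi, egp, intended_bolus, delivered_bolus

    @property
    def infected(self) -> pd.Series:
        return self.frame["infected"]

    def infection_days(self) -> pd.DatetimeIndex:
        return self.frame.index[self.frame["infected"] == 1]

    def to_csv(self, path) -> None:
        self.frame.rename_axis("date").to_csv(path)


MEAL_HOURS = np.arange(7, 22)  # meals drawn between 07:00 and 21:00


def _episode_intensity(episodes: Sequence[EpisodeConfig], day: int, hour: int) -> tuple[float, EpisodeConfig | None]:
    t_days = day + hour / 24.0
    for ep in episodes:
        if ep.onset_day <= t_days < ep.onset_day + ep.duration_days:
            return ep.intensity((t_days - ep.onset_day) / ep.duration_days), ep
    return 0.0, None


def generate_patient_year(config: SimulationConfig) -> tuple[EventLog, GroundTruth]:
    """Simulate one patient-year; identical config (incl. seed) gives identical output."""
    rng = np.random.default_rng(config.seed)
    k_i = K_C / config.baseline_ratio  # mg/dL per unit at phi = 1
    n_hours = config.days * 24

    # Behavioural draws, one block per day so parameter changes that do not
    # alter the number of draws keep the stream aligned across configs.
    n_meals = rng.integers(config.meals_per_day[0], config.meals_per_day[1] + 1, size=config.days)
    planned_carbs = np.clip(
        rng.normal(config.daily_carbs_mean, config.daily_carbs_sd, size=config.days), 60.0, None
    )
    meal_hours: list[np.ndarray] = []
    meal_shares: list[np.ndarray] = []
    dose_noise: list[np.ndarray] = []
    for d in range(config.days):
        m = int(n_meals[d])
        meal_hours.append(np.sort(rng.choice(MEAL_HOURS, size=m, replace=False)))
        meal_shares.append(rng.dirichlet(np.full(m, 4.0)))
        dose_noise.append(rng.normal(0.0, DOSE_CV, size=m))
    process_noise = rng.normal(0.0, PROCESS_SD, size=n_hours)

    # CGM sampling grid and dropout.
    step_min = config.cgm_interval_min
    sample_minutes = np.arange(0, config.days * 24 * 60, step_min)
    cgm_noise = rng.normal(0.0, config.noise_sd, size=len(sample_minutes))
    dropout = rng.random(len(sample_minutes)) < config.missing_bg_rate

    glucose: list[GlucoseSample] = []
    insulin: list[InsulinDose] = []
    carbs: list[CarbIntake] = []

    bg = float(config.bg_target)
    bg_by_hour = np.empty(n_hours)
    phi_day = np.ones(config.days)
    egp_day = np.zeros(config.days)
    infected_day = np.zeros(config.days, dtype=int)
    intended_day = np.zeros(config.days)
    delivered_day = np.zeros(config.days)

    for d in range(config.days):
        day_start = SIM_START + pd.Timedelta(days=d)
        hours = meal_hours[d]
        shares = meal_shares[d]
        noise_d = dose_noise[d]
        phi_acc = 0.0
        egp_acc = 0.0
        if config.basal_daily > 0:
            insulin.append(
                InsulinDose(day_start + pd.Timedelta(hours=8), round(config.basal_daily, 2), InsulinKind.BASAL)
            )
        for h in range(24):
            t = d * 24 + h
            intensity, ep = _episode_intensity(config.episodes, d, h)
            phi = 1.0 - (ep.sensitivity_drop if ep else 0.0) * intensity
            egp = (ep.egp_boost if ep else 0.0) * intensity
            phi_acc += phi
            egp_acc += egp
            if ep is not None and intensity > 0:
                infected_day[d] = 1

            ch = 0.0
            dose = 0.0
            for j, mh in enumerate(hours):
                if mh != h:
                    continue
                appetite = 1.0 - (ep.appetite_drop if ep else 0.0) * intensity
                grams = round(planned_carbs[d] * shares[j] * appetite, 1)
                if grams <= 0:
                    continue
                ts = day_start + pd.Timedelta(hours=int(mh))
                carbs.append(CarbIntake(ts, grams))
                ch += grams
                # Insulin need per gram: cover the meal plus the day's extra
                # hepatic output, at the current (reduced) sensitivity.
                need_factor = (1.0 + egp * 24.0 / (K_C * planned_carbs[d] * appetite)) / phi
                comp = ep.compensation if ep else 1.0
                intended_ratio = config.baseline_ratio * need_factor
                delivered_ratio = config.baseline_ratio * (1.0 + comp * (need_factor - 1.0))
                meal_dose = max(0.0, delivered_ratio * grams * (1.0 + noise_d[j]))
                correction = 0.0
                excess = bg - (config.bg_target + CORRECTION_THRESHOLD)
                if excess > 0:
                    correction = comp * excess / (phi * k_i)
                total_dose = round(meal_dose + correction, 2)
                if total_dose > 0:
                    insulin.append(InsulinDose(ts, total_dose, InsulinKind.BOLUS))
                dose += total_dose
                intended_day[d] += intended_ratio * grams + (excess / (phi * k_i) if excess > 0 else 0.0)
                delivered_day[d] += total_dose

            bg = (
                bg
                + K_C * ch
                - phi * k_i * dose
                + egp
                - K_D * (bg - config.bg_target)
                + process_noise[t]
            )
            bg = float(np.clip(bg, 40.0, 500.0))
            bg_by_hour[t] = bg
        phi_day[d] = phi_acc / 24.0
        egp_day[d] = egp_acc / 24.0

    # CGM readings: hourly state plus sensor noise, device-clipped.
    for minute, eps, drop in zip(sample_minutes, cgm_noise, dropout):
        if drop:
            continue
        hour_idx = min(int(minute // 60), n_hours - 1)
        value = float(np.clip(bg_by_hour[hour_idx] + eps, 40.0, 400.0))
        glucose.append(
            GlucoseSample(SIM_START + pd.Timedelta(minutes=int(minute)), round(value, 1), GlucoseSource.CGM)
        )

    infections = [
        InfectionEvent(SIM_START + pd.Timedelta(days=ep.onset_day), ep.duration_days, ep.label)
        for ep in config.episodes
    ]
    log = EventLog(
        patient_id=f"sim-{config.seed}",
        glucose=glucose,
        insulin=insulin,
        carbs=carbs,
        infections=infections,
        span=(SIM_START, SIM_START + pd.Timedelta(days=config.days - 1)),
    )
    truth = GroundTruth(
        pd.DataFrame(
            {
                "infected": infected_day,
                "phi": phi_day,
                "egp": egp_day,
                "intended_bolus": intended_day,
                "delivered_bolus": delivered_day,
            },
            index=pd.date_range(SIM_START, periods=config.days, freq="D"),
        )
    )
    return log, truth


# ---------------------------------------------------------------------------
# Published worked-example inputs: weekly summaries of five infection cases
# (flu) in people with type 1 diabetes — mean (SD) of daily blood glucose,
# daily bolus insulin and daily carbohydrate over the preinfection,
# infection and postinfection weeks.  The fifth case logged basal insulin
# but no carbohydrate stream.
# ---------------------------------------------------------------------------

_CASES: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "case-1": {
        "pre": {"bg": (130.74, 16.89), "bolus": (23.39, 4.91), "carbs": (241.11, 57.27)},
        "infection": {"bg": (141.95, 14.37), "bolus": (35.30, 6.11), "carbs": (178.80, 65.69)},
        "post": {"bg": (119.16, 7.39), "bolus": (21.32, 4.61), "carbs": (241.18, 37.63)},
    },
    "case-2": {
        "pre": {"bg": (143.01, 19.53), "bolus": (28.07, 8.85), "carbs": (190.14, 43.93)},
        "infection": {"bg": (155.36, 21.99), "bolus": (41.07, 9.44), "carbs": (161.14, 58.43)},
        "post": {"bg": (126.17, 11.70), "bolus": (25.36, 6.93), "carbs": (214.57, 34.66)},
    },
    "case-3": {
        "pre": {"bg": (136.93, 18.58), "bolus": (20.08, 5.44), "carbs": (178.0, 45.87)},
        "infection": {"bg": (144.12, 20.30), "bolus": (31.50, 10.84), "carbs": (144.83, 37.63)},
        "post": {"bg": (134.18, 11.96), "bolus": (22.83, 3.86), "carbs": (195.83, 42.59)},
    },
    "case-4": {
        "pre": {"bg": (157.74, 31.12), "bolus": (24.43, 5.26), "carbs": (199.06, 53.45)},
        "infection": {"bg": (161.34, 19.88), "bolus": (32.14, 7.01), "carbs": (167.04, 44.94)},
        "post": {"bg": (138.57, 19.83), "bolus": (29.29, 5.22), "carbs": (226.07, 18.23)},
    },
    "case-5": {
        "pre": {"bg": (135.21, 14.58), "bolus": (32.80, 4.59), "basal": (19.20, 1.21), "total": (52.33, 5.14)},
        "infection": {"bg": (139.88, 15.54), "bolus": (40.37, 8.31), "basal": (20.42, 2.06), "total": (61.21, 8.26)},
        "post": {"bg": (122.87, 14.49), "bolus": (33.36, 7.94), "basal": (18.68, 1.56), "total": (52.46, 8.47)},
    },
}

#: Per-case percentage changes as published (pre side, post side); the ratio
#: increases are relative to each patient's normal operating point and were
#: published for four of the five cases.
REPORTED_CHANGES: dict[str, dict[str, tuple[float, float]]] = {
    "bg": {
        "case-1": (8.57, 19.12),
        "case-2": (8.63, 23.13),
        "case-3": (7.26, 7.41),
        "case-4": (2.28, 16.43),
        "case-5": (3.45, 13.84),
    },
    "bolus": {
        "case-1": (50.93, 65.59),
        "case-2": (46.31, 61.94),
        "case-3": (56.87, 37.98),
        "case-4": (31.56, 9.7),
        "case-5": (23.08, 21.01),
    },
    "carbs": {
        "case-1": (25.84, 25.87),
        "case-2": (15.25, 24.90),
        "case-3": (18.63, 26.04),
        "case-4": (16.09, 35.34),
    },
}

REPORTED_RATIO_INCREASES: dict[str, float] = {
    "case-1": 125.84,
    "case-2": 144.43,
    "case-3": 93.75,
    "case-4": 70.84,
}


def reference_cases() -> dict[str, dict[str, WeekSummary]]:
    """The five published infection cases as pre/infection/post week summaries."""
    out: dict[str, dict[str, WeekSummary]] = {}
    for case_id, weeks in _CASES.items():
        out[case_id] = {}
        for week, values in weeks.items():
            kwargs: dict = {}
            if "carbs" in values:
                kwargs["carb_mean"], kwargs["carb_sd"] = values["carbs"]
            if "basal" in values:
                kwargs["basal_mean"], kwargs["basal_sd"] = values["basal"]
            if "total" in values:
                kwargs["total_insulin_mean"], kwargs["total_insulin_sd"] = values["total"]
            out[case_id][week] = WeekSummary(
                window_start=None,
                bg_mean=values["bg"][0],
                bg_sd=values["bg"][1],
                bolus_mean=values["bolus"][0],
                bolus_sd=values["bolus"][1],
                **kwargs,
            )
    return out
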