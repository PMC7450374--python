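"""Shared fixtures: simulated patient-years and the 20-seed evaluation battery."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from glycosurv import (
    SimulationConfig,
    case_report,
    generate_patient_year,
    preprocess,
    ratio_shift,
)
from glycosurv.detection import detect, evaluate
from glycosurv.preprocessing import DAY

N_SEEDS = 20
RATIO_BAND = (0.05, 0.2)


@pytest.fixture(scope="session")
def episode_year():
    """One simulated year with a default infection episode (seed 7)."""
    config = SimulationConfig(seed=7).with_default_episode(onset_day=180)
    log, truth = generate_patient_year(config)
    binned, smoothed = preprocess(log, DAY)
    return config, log, truth, binned, smoothed


@pytest.fixture(scope="session")
def null_year():
    """One simulated year without any infection episode (seed 7)."""
    config = SimulationConfig(seed=7)
    log, truth = generate_patient_year(config)
    binned, smoothed = preprocess(log, DAY)
    return config, log, truth, binned, smoothed


def _episode_stats(seed: int) -> dict:
    config = SimulationConfig(seed=seed).with_default_episode(onset_day=180)
    log, truth = generate_patient_year(config)
    binned, smoothed = preprocess(log, DAY)
    ep = log.infections[0]
    reports = {r.parameter.value: r for r in case_report(log, ep, series=binned)}
    scores, status = detect(smoothed, log.infections)
    metrics = evaluate(status, truth)
    infected_days = truth.infection_days()
    day_index = smoothed.bins.normalize()
    episode_scores = scores.values[day_index.isin(infected_days)]
    normal_scores = scores.values[~day_index.isin(infected_days)]
    return {
        "bg_pct_pre": reports["bg"].pct_vs_pre,
        "bolus_pct_pre": reports["bolus"].pct_vs_pre,
        "carbs_pct_pre": reports["carbs"].pct_vs_pre,
        "ratio_peak": float(smoothed.frame["ratio_bolus"].max()),
        "ratio_shift": ratio_shift(smoothed, ep, log.infections),
        "sensitivity": metrics.sensitivity,
        "fpr": metrics.false_positive_rate,
        "episode_score_min": float(np.min(episode_scores)),
        "normal_score_median": float(np.median(normal_scores)),
    }


def _null_stats(seed: int) -> dict:
    from glycosurv.data_model import InfectionEvent

    config = SimulationConfig(seed=seed)
    log, truth = generate_patient_year(config)
    binned, smoothed = preprocess(log, DAY)
    ratios = smoothed.frame["ratio_bolus"].dropna()
    band = float(((ratios >= RATIO_BAND[0]) & (ratios <= RATIO_BAND[1])).mean())
    placebo = InfectionEvent(onset=log.span[0] + pd.Timedelta(days=180), duration_days=10)
    reports = case_report(log, placebo, series=binned)
    pcts = [abs(p) for r in reports for p in (r.pct_vs_pre, r.pct_vs_post)]
    _, status = detect(smoothed, [])
    return {
        "band_fraction": band,
        "mean_abs_pct": float(np.mean(pcts)),
        "flag_rate": float((status.values == 1).mean()),
    }


@pytest.fixture(scope="session")
def episode_battery() -> pd.DataFrame:
    """Episode-year statistics over seeds 0..N_SEEDS-1."""
    return pd.DataFrame([_episode_stats(seed) for seed in range(N_SEEDS)])


@pytest.fixture(scope="session")
def null_battery() -> pd.DataFrame:
    """Null-year (no episode) statistics over seeds 0..N_SEEDS-1."""
    return pd.DataFrame([_null_stats(seed) for seed in range(N_SEEDS)])
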