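"""Heat-stress phenotype derivation: THI, THI load, focal days, the thermal
stress slope (TSS), and hair-length phenotypes.

The temperature-humidity index combines dry-bulb air temperature T (deg C)
and relative humidity RH (%):

    THI = (1.8 T + 32) - (0.55 - 0.0055 RH) (1.8 T - 26)

the standard livestock heat-stress index (the first term is the Fahrenheit
dry-bulb temperature; the correction vanishes at RH = 100).  The daily THI
load is the sum over hours of the THI excess above a baseline of 70; hours
at or below the baseline contribute nothing.

TSS for an animal on its focal day is the diurnal vaginal-temperature range
divided by the THI load, scaled by 100:

    TSS = (VTmax - VTmin) / sum_i max(THI_i - 70, 0) * 100

Lower TSS means steadier core temperature per unit of heat load, i.e. better
thermoregulation.  The focal day for a collection group is the rain-free day
with the highest THI load.  VT extrema are taken over the raw 15-minute
logger records of that day; hourly averaging is used only to match VT to THI.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

THI_BASELINE = 70.0
PIXEL_TO_MM = 2.145 / 1000.0  # image scale: 1,000 pixels = 2.145 mm


class ThermoError(ValueError):
    pass


class ShortDeploymentError(ThermoError):
    """Fewer than 3 calendar days of logger data (nothing left after trim)."""


class NoEligibleDayError(ThermoError):
    """No rain-free day with positive THI load among the candidates."""


@dataclass
class TssRecord:
    """Per-animal thermal stress slope and its ingredients."""

    animal_id: str
    focal_date: date
    vt_max: float
    vt_min: float
    thi_load: float
    tss: float  # NaN when the THI load is zero (TSS undefined)


def compute_thi(air_temperature, relative_humidity):
    """Temperature-humidity index from T (deg C) and RH (%), vectorized."""
    t = np.asarray(air_temperature, dtype=float)
    rh = np.asarray(relative_humidity, dtype=float)
    if ((rh < 0) | (rh > 100)).any():
        raise ThermoError("relative humidity must be within [0, 100]%")
    thi = (1.8 * t + 32.0) - (0.55 - 0.0055 * rh) * (1.8 * t - 26.0)
    return thi if thi.shape else float(thi)


def trim_deployment_days(series: pd.DataFrame, value_col: str = "vaginal_temperature") -> pd.DataFrame:
    """Drop the first and last calendar day of each animal's logger series.

    Those days correspond to device insertion and removal and carry handling
    artifacts.  Requires at least 3 calendar days per animal.
    """
    if "animal_id" in series.columns:
        parts = [g for _, g in series.groupby("animal_id", sort=False)]
    else:
        parts = [series]
    out = []
    for g in parts:
        days = pd.to_datetime(g["timestamp"]).dt.date
        uniq = sorted(days.unique())
        if len(uniq) < 3:
            raise ShortDeploymentError(
                f"need >= 3 calendar days to trim deployment days, got {len(uniq)}"
            )
        out.append(g[(days != uniq[0]) & (days != uniq[-1])])
    return pd.concat(out, ignore_index=True)


def hourly_average(series: pd.DataFrame, value_col: str) -> pd.DataFrame:
    """Arithmetic mean of records per clock hour [h:00, h+1:00).

    Hours with no record are absent from the output.  Grouped per animal if
    an ``animal_id`` column is present.
    """
    df = series.copy()
    df["hour"] = pd.to_datetime(df["timestamp"]).dt.floor("h")
    keys = ["animal_id", "hour"] if "animal_id" in df.columns else ["hour"]
    out = df.groupby(keys, sort=True, as_index=False)[value_col].mean()
    return out


def thi_load(hourly_thi, baseline: float = THI_BASELINE) -> float:
    """Cumulative hourly THI excess above the baseline (deviations below the
    baseline are clamped at zero)."""
    thi = np.asarray(hourly_thi, dtype=float)
    return float(np.maximum(thi - baseline, 0.0).sum())


def daily_thi_loads(env: pd.DataFrame, baseline: float = THI_BASELINE) -> pd.DataFrame:
    """Per-day THI load and rain flag from an environment series.

    The input needs ``timestamp`` and ``thi`` columns (see
    :func:`compute_thi`) and a per-record or per-day ``rain`` flag; THI is
    averaged per hour before the load is summed.
    """
    hourly = hourly_average(env[["timestamp", "thi"]], "thi")
    hourly["day"] = hourly["hour"].dt.date
    loads = hourly.groupby("day")["thi"].apply(lambda v: thi_load(v, baseline)).rename("thi_load")
    rain = env.assign(day=pd.to_datetime(env["timestamp"]).dt.date).groupby("day")["rain"].any()
    return pd.concat([loads, rain], axis=1).reset_index()


def select_focal_day(env: pd.DataFrame, candidate_days=None, baseline: float = THI_BASELINE) -> date:
    """Rain-free day with the maximum THI load; ties go to the earliest date."""
    table = daily_thi_loads(env, baseline)
    if candidate_days is not None:
        candidate_days = {pd.Timestamp(d).date() for d in candidate_days}
        table = table[table["day"].isin(candidate_days)]
    eligible = table[(~table["rain"]) & (table["thi_load"] > 0)]
    if len(eligible) == 0:
        raise NoEligibleDayError("no rain-free day with positive THI load")
    eligible = eligible.sort_values(["thi_load", "day"], ascending=[False, True], kind="mergesort")
    best = eligible.iloc[0]
    # sort is descending on load; among equal loads mergesort keeps date order,
    # but make the earliest-date tie rule explicit:
    top = eligible[eligible["thi_load"] == best["thi_load"]]
    return min(top["day"])


def compute_tss(
    vt_day: pd.DataFrame,
    hourly_thi_day,
    animal_id: str | None = None,
    baseline: float = THI_BASELINE,
    min_records: int = 24,
) -> TssRecord:
    """TSS from one animal's raw focal-day VT records and that day's hourly THI.

    VT extrema are taken over the raw 15-min records.  A zero THI load leaves
    TSS undefined; the record then carries ``tss = NaN`` (missing, not zero).
    """
    vt = np.asarray(vt_day["vaginal_temperature"], dtype=float)
    if len(vt) < min_records:
        raise ThermoError(f"need >= {min_records} VT records in the focal day, got {len(vt)}")
    if animal_id is None:
        ids = vt_day["animal_id"].unique() if "animal_id" in vt_day.columns else ["?"]
        animal_id = str(ids[0])
    focal = pd.to_datetime(vt_day["timestamp"]).dt.date.iloc[0]
    load = thi_load(hourly_thi_day, baseline)
    vt_max, vt_min = float(vt.max()), float(vt.min())
    tss = (vt_max - vt_min) / load * 100.0 if load > 0 else float("nan")
    return TssRecord(animal_id, focal, vt_max, vt_min, load, tss)


def derive_tss(
    temperature: pd.DataFrame,
    env: pd.DataFrame,
    baseline: float = THI_BASELINE,
) -> pd.DataFrame:
    """End-to-end TSS derivation for a cohort sharing one environment series.

    Trims deployment days, computes THI, picks the focal day, and returns one
    row per animal: animal_id, focal_date, vt_max, vt_min, thi_load, tss.
    """
    env = env.copy()
    if "thi" not in env.columns:
        env["thi"] = compute_thi(env["air_temperature"], env["relative_humidity"])
    trimmed = trim_deployment_days(temperature)
    interior_days = set(pd.to_datetime(trimmed["timestamp"]).dt.date.unique())
    focal = select_focal_day(env, candidate_days=interior_days, baseline=baseline)

    hourly = hourly_average(env[["timestamp", "thi"]], "thi")
    hourly_focal = hourly[hourly["hour"].dt.date == focal]["thi"]

    records = []
    for aid, g in trimmed.groupby("animal_id", sort=True):
        day_mask = pd.to_datetime(g["timestamp"]).dt.date == focal
        records.append(compute_tss(g[day_mask], hourly_focal, animal_id=aid, baseline=baseline))
    return pd.DataFrame([r.__dict__ for r in records])


def pixels_to_mm(pixels):
    """Convert image-measured lengths from pixels to millimetres."""
    px = np.asarray(pixels, dtype=float)
    if (px < 0).any():
        raise ThermoError("pixel counts must be non-negative")
    mm = px * PIXEL_TO_MM
    return mm if mm.shape else float(mm)


def filter_hair_outliers(lengths) -> np.ndarray:
    """Drop hair lengths more than 3 SD from the cohort mean of a hair class.

    A single pass over the pooled measurements of one hair class; mean and SD
    (population SD) are computed over the whole cohort, not per animal.
    Returns a boolean keep-mask aligned to the input.
    """
    x = np.asarray(lengths, dtype=float)
    if x.size < 2:
        raise ThermoError("need >= 2 measurements to assess outliers")
    mu, sd = x.mean(), x.std()
    if sd == 0:
        return np.ones_like(x, dtype=bool)
    return np.abs(x - mu) <= 3.0 * sd


def hair_phenotype(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-animal hair-length phenotypes (SHL/LHL) after cohort-level 3-SD QC.

    ``measurements`` is long-format with columns animal_id, hair_class
    ({short, long}), length_mm.  Animals whose measurements were all removed
    get a missing (NaN) phenotype.
    """
    out = []
    for cls, g in measurements.groupby("hair_class", sort=True):
        keep = filter_hair_outliers(g["length_mm"].to_numpy())
        kept = g[keep]
        mean = kept.groupby("animal_id")["length_mm"].mean()
        mean = mean.reindex(g["animal_id"].unique())
        for aid, val in mean.items():
            out.append({"animal_id": aid, "hair_class": cls, "value": val})
    return pd.DataFrame(out)


def coefficient_of_variation(mean: float, sd: float) -> float:
    """CV in percent, the dispersion summary used for trait descriptives."""
    return sd / mean * 100.0


def descriptive_stats(values: pd.Series | np.ndarray) -> dict:
    """N, mean, SD, min, max and CV% for one trait's phenotype vector."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    mean, sd = float(x.mean()), float(x.std(ddof=1))
    return {
        "n": int(x.size),
        "mean": mean,
        "sd": sd,
        "min": float(x.min()),
        "max": float(x.max()),
        "cv_percent": coefficient_of_variation(mean, sd),
    }
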