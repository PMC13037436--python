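"""Nonparametric rest–activity metrics (IS, IV, RA) and the Circadian
Function Index, CFI = (IS + (2 − IV)/2 + RA) / 3.

Activity is binned hourly (p = 24 bins/day) with a wear-majority rule:
an hour counts as valid if at least half of its epochs are worn; invalid
hours are imputed with the across-day mean of the same clock hour. IV is
clamped to [0, 2] before entering the CFI so the index stays in [0, 1];
the raw value is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gutrhythm.datamodel import ActivitySeries, InfantAgeKey
from gutrhythm.errors import InsufficientDataError

HOURS_PER_DAY = 24
MIN_DAYS_DEFAULT = 3


@dataclass
class HourlySeries:
    values: np.ndarray  # imputed hourly means, whole days
    clock_hours: np.ndarray  # hour-of-day label per bin
    valid: np.ndarray  # bool: wear-majority rule met before imputation
    n_days: int


@dataclass
class CircadianMetrics:
    key: InfantAgeKey | None
    n_days: int
    n_hour_bins: int
    IS: float | None
    IV_raw: float | None
    IV: float | None
    M10: float | None
    L5: float | None
    RA: float | None
    CFI: float | None
    note: str = ""


def bin_hourly(
    series: ActivitySeries,
    min_wear_fraction: float = 0.5,
    min_days: int = MIN_DAYS_DEFAULT,
) -> HourlySeries:
    """Hourly wear-weighted means over whole days.

    Leading/trailing partial hours are dropped, then the series is truncated
    to a whole number of days. Raises :class:`InsufficientDataError` when
    fewer than ``min_days × 24`` valid-majority hours remain (the
    at-least-three-continuous-days rule).
    """
    per_hour = 60 // series.epoch_minutes
    n = len(series.epoch_start)
    # drop leading epochs until an hour boundary
    start = 0
    while start < n and (
        series.epoch_start[start].minute % 60 != 0
        or series.epoch_start[start].second != 0
    ):
        start += 1
    n_hours = (n - start) // per_hour
    n_days = n_hours // HOURS_PER_DAY
    n_hours = n_days * HOURS_PER_DAY
    if n_days < min_days:
        raise InsufficientDataError(
            f"{n_days} whole days of actimetry < the {min_days} continuous "
            "days required"
        )
    act = series.activity[start : start + n_hours * per_hour].reshape(n_hours, per_hour)
    wear = series.wear[start : start + n_hours * per_hour].reshape(n_hours, per_hour)
    wear_frac = wear.mean(axis=1)
    valid = wear_frac >= min_wear_fraction
    if int(valid.sum()) < min_days * HOURS_PER_DAY:
        raise InsufficientDataError(
            f"{int(valid.sum())} valid-majority hours < "
            f"{min_days * HOURS_PER_DAY} (at least {min_days} continuous days "
            "of wear required)"
        )
    with np.errstate(invalid="ignore"):
        sums = np.where(wear, act, 0.0).sum(axis=1)
        nwear = wear.sum(axis=1)
        hourly = np.where(nwear > 0, sums / np.maximum(nwear, 1), np.nan)
    clock = np.array(
        [
            (series.epoch_start[start].hour + h) % HOURS_PER_DAY
            for h in range(n_hours)
        ]
    )
    # impute invalid hours by the across-day mean of the same clock hour
    values = hourly.copy()
    overall = np.nanmean(np.where(valid, hourly, np.nan))
    for h in range(HOURS_PER_DAY):
        sel = clock == h
        good = sel & valid & ~np.isnan(hourly)
        fill = hourly[good].mean() if good.any() else overall
        bad = sel & (~valid | np.isnan(hourly))
        values[bad] = fill
    return HourlySeries(values=values, clock_hours=clock, valid=valid, n_days=n_days)


def hourly_from_values(values: np.ndarray, start_clock_hour: int = 0) -> HourlySeries:
    """Wrap an already-binned hourly sequence spanning whole days."""
    values = np.asarray(values, dtype=float)
    if values.size % HOURS_PER_DAY != 0:
        raise ValueError("hourly series must span whole days")
    clock = (start_clock_hour + np.arange(values.size)) % HOURS_PER_DAY
    return HourlySeries(
        values=values,
        clock_hours=clock,
        valid=np.ones(values.size, dtype=bool),
        n_days=values.size // HOURS_PER_DAY,
    )


def _clock_hour_means(hourly: HourlySeries) -> np.ndarray:
    means = np.empty(HOURS_PER_DAY)
    for h in range(HOURS_PER_DAY):
        means[h] = hourly.values[hourly.clock_hours == h].mean()
    return means


def interdaily_stability(hourly: HourlySeries) -> float | None:
    """IS = (n·Σ_h (x̄_h − x̄)²) / (p·Σ_i (xᵢ − x̄)²); missing for a constant
    series."""
    x = hourly.values
    n = x.size
    xbar = x.mean()
    ss_tot = ((x - xbar) ** 2).sum()
    if ss_tot == 0.0:
        return None
    hmeans = _clock_hour_means(hourly)
    num = n * ((hmeans - xbar) ** 2).sum()
    return float(min(max(num / (HOURS_PER_DAY * ss_tot), 0.0), 1.0))


def intradaily_variability(hourly: HourlySeries) -> tuple[float | None, float | None]:
    """(IV_raw, IV clamped to [0, 2]); missing for a constant series."""
    x = hourly.values
    n = x.size
    xbar = x.mean()
    ss_tot = ((x - xbar) ** 2).sum()
    if ss_tot == 0.0:
        return None, None
    num = n * (np.diff(x) ** 2).sum()
    iv_raw = float(num / ((n - 1) * ss_tot))
    return iv_raw, float(min(max(iv_raw, 0.0), 2.0))


def relative_amplitude(hourly: HourlySeries) -> tuple[float, float, float]:
    """(RA, M10, L5) from the average 24-h profile with circular windows."""
    profile = _clock_hour_means(hourly)
    ext = np.concatenate([profile, profile])
    w10 = np.array([ext[i : i + 10].mean() for i in range(HOURS_PER_DAY)])
    w5 = np.array([ext[i : i + 5].mean() for i in range(HOURS_PER_DAY)])
    m10 = float(w10.max())
    l5 = float(w5.min())
    ra = 0.0 if m10 + l5 == 0 else (m10 - l5) / (m10 + l5)
    return float(ra), m10, l5


def compose_cfi(IS: float, IV: float, RA: float) -> float:
    return (IS + (2.0 - IV) / 2.0 + RA) / 3.0


def circadian_function_index(
    series: ActivitySeries,
    min_wear_fraction: float = 0.5,
    min_days: int = MIN_DAYS_DEFAULT,
) -> CircadianMetrics:
    """Full metric set for one infant-age activity series."""
    hourly = bin_hourly(series, min_wear_fraction, min_days)
    IS = interdaily_stability(hourly)
    iv_raw, IV = intradaily_variability(hourly)
    RA, M10, L5 = relative_amplitude(hourly)
    if IS is None or IV is None:
        cfi = None
        note = "constant activity: IS/IV undefined"
    else:
        cfi = compose_cfi(IS, IV, RA)
        note = ""
    return CircadianMetrics(
        key=series.key,
        n_days=hourly.n_days,
        n_hour_bins=int(hourly.values.size),
        IS=IS,
        IV_raw=iv_raw,
        IV=IV,
        M10=M10,
        L5=L5,
        RA=RA,
        CFI=cfi,
        note=note,
    )
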