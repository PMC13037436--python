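"""Sleep-quality composite (BabySQUID) and diary-derived covariates.

BabySQUID per infant-age: the four BISQ variables (nighttime sleep
duration, sleep-onset latency, bedtime, number of awakenings) are
median-imputed for records with at most two missing values (records with
three or more missing are excluded), min-max scaled over the whole
included cohort, reverse-coded except for sleep duration, and averaged
with equal weights into a 0–1 score.

Diary covariates per stool sample: time awake before sampling, duration of
the preceding sleep bout, time since last feeding, time since the previous
stool sample of the same infant-age. Feeding rhythmicity per infant-age:
day-level SD of inter-feeding intervals, aggregated across days.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from statistics import median
from typing import Mapping, Sequence

import numpy as np

from gutrhythm.datamodel import (
    DiaryTimeline,
    InfantAgeKey,
    QuestionnaireRecord,
    SampleRecord,
)
from gutrhythm.errors import GutRhythmError

BISQ_VARS = (
    "bisq_night_sleep_h",
    "bisq_latency_h",
    "bisq_bedtime_clock_h",
    "bisq_n_awakenings",
)
REVERSED_VARS = ("bisq_latency_h", "bisq_bedtime_clock_h", "bisq_n_awakenings")


@dataclass
class SleepQualityRecord:
    key: InfantAgeKey
    duration_scaled: float
    latency_rev: float
    bedtime_rev: float
    awakenings_rev: float
    babysquid: float
    n_imputed: int


@dataclass
class SquidExclusion:
    key: InfantAgeKey
    n_missing: int
    reason: str


@dataclass
class HistoryRecord:
    sample_id: str
    prior_awake_h: float | None
    last_sleep_duration_h: float | None
    time_since_feeding_h: float | None
    time_since_last_bowel_movement_h: float | None


@dataclass
class FeedingRhythmicityRecord:
    key: InfantAgeKey
    value: float  # mean (or median) of day-level interval SDs, hours
    n_days: int
    n_days_skipped: int


def compute_babysquid(
    records: Sequence[QuestionnaireRecord],
    max_missing: int = 2,
    max_night_sleep_h: float | None = None,
    max_latency_h: float | None = None,
) -> tuple[list[SleepQualityRecord], list[SquidExclusion]]:
    """Build the BabySQUID composite; see module docstring for the rules.

    Optional plausibility bounds null out implausible raw entries before the
    missingness rule is applied (both default off).
    """
    raw: dict[InfantAgeKey, dict[str, float | None]] = {}
    exclusions: list[SquidExclusion] = []
    for rec in records:
        vals = {v: getattr(rec, v) for v in BISQ_VARS}
        if max_night_sleep_h is not None and vals["bisq_night_sleep_h"] is not None:
            if vals["bisq_night_sleep_h"] > max_night_sleep_h:
                vals["bisq_night_sleep_h"] = None
        if max_latency_h is not None and vals["bisq_latency_h"] is not None:
            if vals["bisq_latency_h"] > max_latency_h:
                vals["bisq_latency_h"] = None
        n_missing = sum(v is None for v in vals.values())
        if n_missing > max_missing:
            exclusions.append(
                SquidExclusion(
                    rec.key, n_missing, f"{n_missing} missing BISQ variables > {max_missing}"
                )
            )
            continue
        raw[rec.key] = vals
    if len(raw) < 2:
        raise GutRhythmError(
            f"min-max scaling needs ≥ 2 included records, got {len(raw)}"
        )
    # cohort medians over non-missing values of included records
    medians: dict[str, float] = {}
    for var in BISQ_VARS:
        present = [v[var] for v in raw.values() if v[var] is not None]
        if not present:
            raise GutRhythmError(f"variable {var} missing for every included record")
        medians[var] = float(median(present))
    imputed_count: dict[InfantAgeKey, int] = {}
    for key, vals in raw.items():
        imputed_count[key] = sum(v is None for v in vals.values())
        for var in BISQ_VARS:
            if vals[var] is None:
                vals[var] = medians[var]
    # min-max scale over all included records; constant variable → 0.5
    scaled: dict[InfantAgeKey, dict[str, float]] = {k: {} for k in raw}
    for var in BISQ_VARS:
        values = np.array([raw[k][var] for k in raw], dtype=float)
        lo, hi = values.min(), values.max()
        for k in raw:
            if hi == lo:
                s = 0.5
            else:
                s = (raw[k][var] - lo) / (hi - lo)
            if var in REVERSED_VARS:
                s = 1.0 - s
            scaled[k][var] = float(s)
    out = [
        SleepQualityRecord(
            key=k,
            duration_scaled=scaled[k]["bisq_night_sleep_h"],
            latency_rev=scaled[k]["bisq_latency_h"],
            bedtime_rev=scaled[k]["bisq_bedtime_clock_h"],
            awakenings_rev=scaled[k]["bisq_n_awakenings"],
            babysquid=float(np.mean([scaled[k][v] for v in BISQ_VARS])),
            n_imputed=imputed_count[k],
        )
        for k in sorted(raw)
    ]
    return out, exclusions


def _hours(a: datetime, b: datetime) -> float:
    return (a - b).total_seconds() / 3600.0


def derive_sample_history(
    samples: Sequence[SampleRecord],
    diaries: Mapping[InfantAgeKey, DiaryTimeline],
) -> list[HistoryRecord]:
    """Sleep/feeding/bowel-movement history relative to each stool sample.

    A sample time on a 15-min boundary belongs to the later interval. For a
    sample during a wake period: prior_awake is time since the last sleep
    bout ended and last_sleep_duration is that bout's length; during sleep:
    prior_awake is 0 and last_sleep_duration is the elapsed time of the
    ongoing bout. Fields outside diary coverage are missing.
    """
    by_key: dict[InfantAgeKey, list[SampleRecord]] = {}
    for rec in samples:
        by_key.setdefault(rec.key, []).append(rec)

    out: list[HistoryRecord] = []
    for key in sorted(by_key):
        recs = sorted(by_key[key], key=lambda r: r.collection_datetime)
        diary = diaries.get(key)
        prev_time: datetime | None = None
        for rec in recs:
            t = rec.collection_datetime
            prior_awake = last_sleep = since_feed = None
            if diary is not None and len(diary.interval_start):
                start = diary.interval_start[0]
                from datetime import timedelta

                end = diary.interval_start[-1] + timedelta(
                    minutes=diary.interval_minutes
                )
                if start <= t < end:
                    bouts = diary.sleep_bouts()
                    ongoing = next(
                        (b for b in bouts if b.start <= t < b.end), None
                    )
                    if ongoing is not None:
                        prior_awake = 0.0
                        last_sleep = _hours(t, ongoing.start)
                    else:
                        past = [b for b in bouts if b.end <= t]
                        if past:
                            last = past[-1]
                            prior_awake = _hours(t, last.end)
                            last_sleep = _hours(last.end, last.start)
            if diary is not None and diary.feed_times:
                feeds_before = [f for f in diary.feed_times if f <= t]
                if feeds_before:
                    since_feed = _hours(t, feeds_before[-1])
            since_bowel = (
                _hours(t, prev_time) if prev_time is not None else None
            )
            out.append(
                HistoryRecord(
                    sample_id=rec.sample_id,
                    prior_awake_h=prior_awake,
                    last_sleep_duration_h=last_sleep,
                    time_since_feeding_h=since_feed,
                    time_since_last_bowel_movement_h=since_bowel,
                )
            )
            prev_time = t
    return out


def feeding_rhythmicity(
    diaries: Mapping[InfantAgeKey, DiaryTimeline],
    aggregation: str = "mean",
) -> list[FeedingRhythmicityRecord]:
    """Per infant-age: day-level sample SD (n−1) of consecutive inter-feeding
    intervals (hours, midnight-to-midnight days), aggregated across days.
    Days with fewer than two intervals are skipped and counted; infant-ages
    with no eligible day yield no record."""
    if aggregation not in ("mean", "median"):
        raise GutRhythmError(f"unknown aggregation {aggregation!r}")
    out: list[FeedingRhythmicityRecord] = []
    for key in sorted(diaries):
        diary = diaries[key]
        by_day: dict = {}
        for f in diary.feed_times:
            by_day.setdefault(f.date(), []).append(f)
        day_sds = []
        skipped = 0
        for day in sorted(by_day):
            feeds = sorted(by_day[day])
            intervals = [
                _hours(b, a) for a, b in zip(feeds[:-1], feeds[1:])
            ]
            if len(intervals) < 2:
                skipped += 1
                continue
            day_sds.append(float(np.std(intervals, ddof=1)))
        if not day_sds:
            continue
        value = float(np.mean(day_sds)) if aggregation == "mean" else float(
            np.median(day_sds)
        )
        out.append(
            FeedingRhythmicityRecord(
                key=key, value=value, n_days=len(day_sds), n_days_skipped=skipped
            )
        )
    return out
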