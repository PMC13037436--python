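from datetime import datetime, timedelta

import numpy as np
import pytest

from gutrhythm.datamodel import DiaryTimeline, InfantAgeKey, QuestionnaireRecord, SampleRecord
from gutrhythm.errors import GutRhythmError
from gutrhythm.sleep_behavior import (
    compute_babysquid,
    derive_sample_history,
    feeding_rhythmicity,
)


def q(iid, dur=None, lat=None, bed=None, awk=None, age=2):
    return QuestionnaireRecord(
        infant_id=iid,
        age_group=age,
        bisq_night_sleep_h=dur,
        bisq_latency_h=lat,
        bisq_bedtime_clock_h=bed,
        bisq_n_awakenings=awk,
    )


# ---------------------------------------------------------------------------
# BabySQUID


def test_worked_three_infant_example():
    records = [
        q("I1", 8, 0.25, 19, 0),
        q("I2", 10, 0.5, 20, 2),
        q("I3", 12, 1.0, 21, 4),
    ]
    out, excl = compute_babysquid(records)
    scores = {r.key.infant_id: r.babysquid for r in out}
    assert scores["I1"] == pytest.approx(0.75, abs=1e-4)
    assert scores["I2"] == pytest.approx(0.5417, abs=1e-4)
    assert scores["I3"] == pytest.approx(0.25, abs=1e-4)
    # infant 1 components: (0 + 1 + 1 + 1)/4
    r1 = next(r for r in out if r.key.infant_id == "I1")
    assert (r1.duration_scaled, r1.latency_rev, r1.bedtime_rev, r1.awakenings_rev) == (
        0.0,
        1.0,
        1.0,
        1.0,
    )


def test_cohort_best_and_worst_endpoints():
    records = [
        q("best", 12, 0.1, 19, 0),
        q("mid", 10, 0.5, 20, 2),
        q("worst", 8, 1.0, 21, 5),
    ]
    out, _ = compute_babysquid(records)
    scores = {r.key.infant_id: r.babysquid for r in out}
    assert scores["best"] == pytest.approx(1.0, abs=1e-12)
    assert scores["worst"] == pytest.approx(0.0, abs=1e-12)


def test_three_missing_excluded():
    records = [q("I1", 8, None, None, None), q("I2", 10, 0.5, 20, 2), q("I3", 9, 0.7, 21, 1)]
    out, excl = compute_babysquid(records)
    assert {r.key.infant_id for r in out} == {"I2", "I3"}
    assert excl[0].key.infant_id == "I1"
    assert excl[0].n_missing == 3


def test_two_missing_median_imputed():
    records = [
        q("I1", 8, None, None, 0),
        q("I2", 10, 0.4, 20, 2),
        q("I3", 12, 0.8, 22, 4),
    ]
    out, _ = compute_babysquid(records)
    r1 = next(r for r in out if r.key.infant_id == "I1")
    assert r1.n_imputed == 2
    # imputed latency = median(0.4, 0.8) = 0.6 → scaled (0.6-0.4)/0.4 = 0.5
    assert r1.latency_rev == pytest.approx(0.5, abs=1e-12)


def test_constant_variable_scales_half():
    records = [q("I1", 9, 0.5, 20, 1), q("I2", 9, 0.7, 21, 2)]
    out, _ = compute_babysquid(records)
    for r in out:
        assert r.duration_scaled == 0.5


def test_affine_invariance():
    base = [q("I1", 8, 0.25, 19, 0), q("I2", 10, 0.5, 20, 2), q("I3", 12, 1.0, 21, 4)]
    out1, _ = compute_babysquid(base)
    scaled = [
        q(r.infant_id, 3 * r.bisq_night_sleep_h + 7, r.bisq_latency_h,
          r.bisq_bedtime_clock_h, r.bisq_n_awakenings)
        for r in base
    ]
    out2, _ = compute_babysquid(scaled)
    for a, b in zip(out1, out2):
        assert a.babysquid == pytest.approx(b.babysquid, abs=1e-12)


def test_reversal_identity():
    base = [q("I1", 8, 0.25, 19, 0), q("I2", 10, 0.5, 20, 2), q("I3", 12, 1.0, 21, 4)]
    out1, _ = compute_babysquid(base)
    # reverse the cohort ranking of awakenings: x → max+min−x
    lo, hi = 0, 4
    flipped = [
        q(r.infant_id, r.bisq_night_sleep_h, r.bisq_latency_h,
          r.bisq_bedtime_clock_h, hi + lo - r.bisq_n_awakenings)
        for r in base
    ]
    out2, _ = compute_babysquid(flipped)
    for a, b in zip(out1, out2):
        assert b.awakenings_rev == pytest.approx(1 - a.awakenings_rev, abs=1e-12)


def test_too_few_records_error():
    with pytest.raises(GutRhythmError):
        compute_babysquid([q("I1", 8, 0.5, 20, 1)])


def test_plausibility_bounds_null_entries():
    records = [q("I1", 16, 0.5, 20, 1), q("I2", 9, 0.7, 21, 2), q("I3", 10, 0.2, 19, 0)]
    out, _ = compute_babysquid(records, max_night_sleep_h=14)
    r1 = next(r for r in out if r.key.infant_id == "I1")
    assert r1.n_imputed == 1  # implausible 16 h nulled then imputed


# ---------------------------------------------------------------------------
# sample history


def mk_diary(key, day=datetime(2024, 1, 1)):
    """Diary 12:00–20:00: sleep 13:00–14:30, wake otherwise; feed 15:00."""
    start = day.replace(hour=12)
    n = 8 * 4
    states = np.zeros(n, dtype=bool)
    for k in range(n):
        t = start + timedelta(minutes=15 * k)
        states[k] = day.replace(hour=13) <= t < day.replace(hour=14, minute=30)
    return DiaryTimeline(
        key=key,
        interval_start=[start + timedelta(minutes=15 * k) for k in range(n)],
        is_sleep=states,
        feed_times=[day.replace(hour=15)],
    )


def mk_sample(sid, when, iid="I1"):
    return SampleRecord(
        sample_id=sid, infant_id=iid, age_group=2, age_days=76,
        collection_datetime=when, sex="female",
    )


def test_history_manual_timeline():
    key = InfantAgeKey("I1", 2)
    diary = mk_diary(key)
    sample = mk_sample("s1", datetime(2024, 1, 1, 16, 0))
    [h] = derive_sample_history([sample], {key: diary})
    assert h.prior_awake_h == pytest.approx(1.5)
    assert h.last_sleep_duration_h == pytest.approx(1.5)
    assert h.time_since_feeding_h == pytest.approx(1.0)
    assert h.time_since_last_bowel_movement_h is None


def test_history_mid_sleep_sample():
    key = InfantAgeKey("I1", 2)
    diary = mk_diary(key)
    sample = mk_sample("s1", datetime(2024, 1, 1, 14, 0))
    [h] = derive_sample_history([sample], {key: diary})
    assert h.prior_awake_h == 0.0
    assert h.last_sleep_duration_h == pytest.approx(1.0)


def test_history_bowel_movement_interval():
    key = InfantAgeKey("I1", 2)
    diary = mk_diary(key)
    s1 = mk_sample("s1", datetime(2024, 1, 1, 8, 0))
    s2 = mk_sample("s2", datetime(2024, 1, 1, 13, 30))
    h1, h2 = derive_sample_history([s1, s2], {key: diary})
    assert h1.time_since_last_bowel_movement_h is None
    assert h2.time_since_last_bowel_movement_h == pytest.approx(5.5)


def test_history_outside_diary_missing():
    key = InfantAgeKey("I1", 2)
    diary = mk_diary(key)
    sample = mk_sample("s1", datetime(2024, 1, 2, 9, 0))
    [h] = derive_sample_history([sample], {key: diary})
    assert h.prior_awake_h is None
    assert h.last_sleep_duration_h is None


def test_history_nonnegative_invariant():
    key = InfantAgeKey("I1", 2)
    diary = mk_diary(key)
    rng = np.random.default_rng(0)
    for _ in range(30):
        minutes = int(rng.integers(0, 8 * 60))
        t = datetime(2024, 1, 1, 12, 0) + timedelta(minutes=minutes)
        [h] = derive_sample_history([mk_sample("s", t)], {key: diary})
        for v in (h.prior_awake_h, h.last_sleep_duration_h, h.time_since_feeding_h):
            assert v is None or v >= 0


# ---------------------------------------------------------------------------
# feeding rhythmicity


def feed_diary(key, feed_times):
    return DiaryTimeline(key=key, interval_start=[], is_sleep=np.zeros(0), feed_times=feed_times)


def test_feeding_equal_intervals_sd_zero():
    key = InfantAgeKey("I1", 2)
    day = datetime(2024, 1, 1)
    feeds = [day + timedelta(hours=h) for h in (8, 11, 14, 17)]
    [rec] = feeding_rhythmicity({key: feed_diary(key, feeds)})
    assert rec.value == pytest.approx(0.0, abs=1e-12)
    assert rec.n_days == 1


def test_feeding_hand_computed_sd():
    key = InfantAgeKey("I1", 2)
    day = datetime(2024, 1, 1)
    feeds = [day + timedelta(hours=h) for h in (6, 8, 11, 15)]  # gaps 2,3,4
    [rec] = feeding_rhythmicity({key: feed_diary(key, feeds)})
    assert rec.value == pytest.approx(1.0, abs=1e-12)


def test_feeding_short_days_skipped():
    key = InfantAgeKey("I1", 2)
    d1 = datetime(2024, 1, 1)
    d2 = datetime(2024, 1, 2)
    feeds = [d1 + timedelta(hours=h) for h in (6, 8, 11, 15)] + [
        d2 + timedelta(hours=9)
    ]
    [rec] = feeding_rhythmicity({key: feed_diary(key, feeds)})
    assert rec.n_days == 1
    assert rec.n_days_skipped == 1


def test_feeding_no_eligible_day_no_record():
    key = InfantAgeKey("I1", 2)
    feeds = [datetime(2024, 1, 1, 9)]
    assert feeding_rhythmicity({key: feed_diary(key, feeds)}) == []


def test_jitter_free_synthetic_diary_all_zero():
    from gutrhythm.config import Config
    from gutrhythm.simulate import simulate_diary_and_questionnaires

    cfg = Config().synthetic
    cfg.n_infants = 3
    cfg.feed_interval_jitter_h = 0.0
    diaries, _, _ = simulate_diary_and_questionnaires(cfg, seed=0)
    records = feeding_rhythmicity(diaries)
    assert records
    for rec in records:
        assert rec.value == pytest.approx(0.0, abs=1e-9)
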