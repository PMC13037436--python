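from datetime import datetime, timedelta

import numpy as np
import pytest

from gutrhythm.actigraphy import (
    bin_hourly,
    circadian_function_index,
    compose_cfi,
    hourly_from_values,
    interdaily_stability,
    intradaily_variability,
    relative_amplitude,
)
from gutrhythm.datamodel import ActivitySeries, InfantAgeKey
from gutrhythm.errors import InsufficientDataError

KEY = InfantAgeKey("I01", 2)
T0 = datetime(2024, 3, 1, 0, 0)


def make_series(activity, wear=None, epoch_minutes=1, start=T0):
    n = len(activity)
    if wear is None:
        wear = np.ones(n, dtype=bool)
    return ActivitySeries(
        key=KEY,
        epoch_start=[start + timedelta(minutes=i * epoch_minutes) for i in range(n)],
        activity=np.asarray(activity, dtype=float),
        wear=np.asarray(wear, dtype=bool),
        epoch_minutes=epoch_minutes,
    )


# ---------------------------------------------------------------------------
# brute-force oracles (independent double-loop formulas)


def is_oracle(x, clock):
    n = len(x)
    xbar = sum(x) / n
    hbar = {}
    for h in range(24):
        vals = [x[i] for i in range(n) if clock[i] == h]
        hbar[h] = sum(vals) / len(vals)
    num = n * sum((hbar[h] - xbar) ** 2 for h in range(24))
    den = 24 * sum((xi - xbar) ** 2 for xi in x)
    return num / den


def iv_oracle(x):
    n = len(x)
    xbar = sum(x) / n
    num = n * sum((x[i] - x[i - 1]) ** 2 for i in range(1, n))
    den = (n - 1) * sum((xi - xbar) ** 2 for xi in x)
    return num / den


def ra_oracle(x, clock):
    prof = [np.mean([x[i] for i in range(len(x)) if clock[i] == h]) for h in range(24)]
    m10 = max(
        np.mean([prof[(s + k) % 24] for k in range(10)]) for s in range(24)
    )
    l5 = min(np.mean([prof[(s + k) % 24] for k in range(5)]) for s in range(24))
    return (m10 - l5) / (m10 + l5), m10, l5


def impute_oracle(activity, wear, per_hour):
    """Per-clock-hour mean imputation, straight from the rule text."""
    n_hours = len(activity) // per_hour
    hourly, valid = [], []
    for h in range(n_hours):
        a = activity[h * per_hour : (h + 1) * per_hour]
        w = wear[h * per_hour : (h + 1) * per_hour]
        valid.append(w.mean() >= 0.5)
        hourly.append(a[w].mean() if w.any() else np.nan)
    out = list(hourly)
    for h in range(n_hours):
        if not valid[h] or np.isnan(hourly[h]):
            peers = [
                hourly[k]
                for k in range(n_hours)
                if k % 24 == h % 24 and valid[k] and not np.isnan(hourly[k])
            ]
            out[h] = np.mean(peers)
    return np.array(out), np.array(valid)


# ---------------------------------------------------------------------------
# bin_hourly


def test_bin_constant_activity():
    series = make_series(np.full(3 * 1440, 5.0))
    hourly = bin_hourly(series)
    assert np.allclose(hourly.values, 5.0)
    assert hourly.n_days == 3


def test_bin_short_series_refused():
    series = make_series(np.ones(2 * 1440))
    with pytest.raises(InsufficientDataError, match="3 continuous days"):
        bin_hourly(series)


def test_bin_invalid_hour_imputed():
    rng = np.random.default_rng(0)
    act = rng.uniform(0, 10, 4 * 1440)
    wear = np.ones_like(act, dtype=bool)
    # hour 5 of day 0: only 40% wear → invalid
    wear[5 * 60 : 5 * 60 + 36] = False
    series = make_series(act, wear)
    hourly = bin_hourly(series)
    assert not hourly.valid[5]
    peers = [hourly.values[5 + 24 * d] for d in (1, 2, 3)]
    assert hourly.values[5] == pytest.approx(np.mean(peers), abs=1e-12)


def test_bin_matches_imputation_oracle():
    rng = np.random.default_rng(1)
    act = rng.uniform(0, 10, 4 * 1440)
    wear = rng.random(4 * 1440) > 0.1
    series = make_series(act, wear)
    hourly = bin_hourly(series)
    expected, valid = impute_oracle(act, wear, 60)
    assert np.array_equal(hourly.valid, valid)
    assert np.allclose(hourly.values, expected, atol=1e-12)


def test_bin_trims_partial_hours():
    # start 00:30 → first half hour dropped, then whole days kept
    act = np.ones(3 * 1440 + 30)
    series = make_series(act, start=datetime(2024, 3, 1, 0, 30))
    hourly = bin_hourly(series)
    assert hourly.values.size == 3 * 24
    assert hourly.clock_hours[0] == 1


# ---------------------------------------------------------------------------
# IS / IV / RA


def test_is_perfect_repetition():
    rng = np.random.default_rng(2)
    day = rng.uniform(0, 10, 24)
    hourly = hourly_from_values(np.tile(day, 5))
    assert interdaily_stability(hourly) == pytest.approx(1.0, abs=1e-12)


def test_is_iid_noise_expectation():
    rng = np.random.default_rng(3)
    vals = [
        interdaily_stability(hourly_from_values(rng.normal(size=7 * 24)))
        for _ in range(200)
    ]
    assert np.mean(vals) == pytest.approx(1 / 7, abs=0.05)


def test_iv_iid_noise_expectation():
    rng = np.random.default_rng(4)
    vals = [
        intradaily_variability(hourly_from_values(rng.normal(size=7 * 24)))[0]
        for _ in range(200)
    ]
    assert np.mean(vals) == pytest.approx(2.0, abs=0.1)


def test_iv_smooth_sinusoid():
    t = np.arange(5 * 24)
    x = 10 + np.sin(2 * np.pi * t / 24)
    iv_raw, iv = intradaily_variability(hourly_from_values(x))
    assert iv_raw == pytest.approx(2 * (1 - np.cos(np.pi / 12)), rel=0.05)
    assert iv_raw < 0.1


def test_iv_alternating_clamped():
    x = np.tile([0.0, 1.0], 3 * 12)
    iv_raw, iv = intradaily_variability(hourly_from_values(x))
    assert iv_raw == pytest.approx(4.0, rel=0.05)
    assert iv == 2.0


def test_metrics_match_oracles_random():
    rng = np.random.default_rng(5)
    for _ in range(100):
        days = int(rng.integers(3, 8))
        x = rng.uniform(0, 50, days * 24)
        start = int(rng.integers(0, 24))
        hourly = hourly_from_values(x, start_clock_hour=start)
        clock = list(hourly.clock_hours)
        assert interdaily_stability(hourly) == pytest.approx(
            is_oracle(x, clock), abs=1e-12
        )
        assert intradaily_variability(hourly)[0] == pytest.approx(
            iv_oracle(x), abs=1e-12
        )
        ra, m10, l5 = relative_amplitude(hourly)
        ra_o, m10_o, l5_o = ra_oracle(x, clock)
        assert ra == pytest.approx(ra_o, abs=1e-12)
        assert m10 == pytest.approx(m10_o, abs=1e-12)
        assert l5 == pytest.approx(l5_o, abs=1e-12)


def test_ra_square_wave():
    day = np.zeros(24)
    day[8:18] = 100.0
    ra, m10, l5 = relative_amplitude(hourly_from_values(np.tile(day, 3)))
    assert (m10, l5, ra) == (100.0, 0.0, 1.0)


def test_ra_constant_zero():
    ra, _, _ = relative_amplitude(hourly_from_values(np.full(3 * 24, 7.0)))
    assert ra == 0.0


def test_invariances():
    rng = np.random.default_rng(6)
    x = rng.uniform(0, 10, 5 * 24)
    h = hourly_from_values(x)
    for a, b in [(3.0, 5.0), (0.5, -1.0)]:
        h2 = hourly_from_values(a * x + b)
        assert interdaily_stability(h2) == pytest.approx(
            interdaily_stability(h), abs=1e-10
        )
        assert intradaily_variability(h2)[0] == pytest.approx(
            intradaily_variability(h)[0], abs=1e-10
        )
    # RA invariant to positive scaling only
    assert relative_amplitude(hourly_from_values(4.2 * x))[0] == pytest.approx(
        relative_amplitude(h)[0], abs=1e-10
    )


# ---------------------------------------------------------------------------
# CFI


def test_cfi_extremes():
    assert compose_cfi(1.0, 0.0, 1.0) == 1.0
    assert compose_cfi(0.0, 2.0, 0.0) == 0.0


def test_cfi_full_series():
    # repeating square-wave day: IS = 1, RA = 1, IV small → CFI near 1
    day = np.zeros(1440)
    day[8 * 60 : 18 * 60] = 100.0
    series = make_series(np.tile(day, 4))
    m = circadian_function_index(series)
    assert m.IS == pytest.approx(1.0, abs=1e-9)
    assert m.RA == pytest.approx(1.0, abs=1e-12)
    assert m.CFI == pytest.approx(compose_cfi(m.IS, m.IV, m.RA), abs=1e-15)
    assert 0.0 <= m.CFI <= 1.0


def test_cfi_constant_missing():
    m = circadian_function_index(make_series(np.full(3 * 1440, 4.0)))
    assert m.CFI is None and m.IS is None


def test_cfi_bounds_random():
    rng = np.random.default_rng(7)
    for _ in range(10):
        act = rng.uniform(0, 30, 3 * 1440)
        m = circadian_function_index(make_series(act))
        assert 0.0 <= m.CFI <= 1.0


def test_cfi_decreases_with_fragmentation():
    from gutrhythm.config import Config
    from gutrhythm.simulate import simulate_actigraphy

    means = []
    for frag in (0.0, 0.2, 0.5):
        cfg = Config().synthetic
        cfg.n_infants = 2
        cfg.fragmentation_per_h = frag
        vals = []
        for seed in range(10):
            series, _ = simulate_actigraphy(cfg, seed)
            for s in series.values():
                vals.append(circadian_function_index(s).CFI)
        means.append(np.mean(vals))
    assert means[0] > means[1] > means[2]


def test_iv_increases_with_fragmentation():
    from gutrhythm.config import Config
    from gutrhythm.simulate import simulate_actigraphy

    means = []
    for frag in (0.0, 0.2, 0.5):
        cfg = Config().synthetic
        cfg.n_infants = 2
        cfg.fragmentation_per_h = frag
        vals = []
        for seed in range(10):
            series, _ = simulate_actigraphy(cfg, seed)
            for s in series.values():
                hourly = bin_hourly(s)
                vals.append(intradaily_variability(hourly)[0])
        means.append(np.mean(vals))
    assert means[0] < means[1] < means[2]
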