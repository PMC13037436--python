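"""Fixed-period 24-h cosinor fits of diversity and genus series.

The model ``y = C + A·cos(ωt + φ)`` with ``ω = 2π/24`` is linear in
``(C, a, b)`` after the substitution ``y = C + a·cos(ωt) + b·sin(ωt)``,
so the fit is exact ordinary least squares with ``A = √(a² + b²)`` and
``φ = atan2(−b, a)``. Rhythmicity is the plain (unadjusted) R² of the fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from typing import Sequence

import numpy as np
import pandas as pd

from gutrhythm.datamodel import ALPHA_METRICS, InfantAgeKey, SampleRecord
from gutrhythm.diversity import AlphaResult
from gutrhythm.errors import InsufficientDataError, RankDeficiencyError

MIN_SAMPLES_DEFAULT = 4
PERIOD_H = 24.0


@dataclass
class CosinorFit:
    """One cosine fit for one (infant, age) series of one target variable."""

    key: InfantAgeKey | None
    target: str
    n_samples: int
    amplitude: float
    acrophase_rad: float  # in (−π, π]
    peak_hour: float  # clock hour of fitted maximum, in [0, 24)
    mesor: float
    r_squared: float | None  # missing iff the series has zero variance


@dataclass
class RhythmicityExclusion:
    key: InfantAgeKey
    target: str
    n_samples: int
    reason: str


def fit_cosinor(
    times_h: Sequence[float],
    values: Sequence[float],
    min_samples: int = MIN_SAMPLES_DEFAULT,
    period_h: float = PERIOD_H,
) -> CosinorFit:
    """Least-squares cosinor fit at fixed period (default 24 h).

    Raises
    ------
    InsufficientDataError
        if fewer than *min_samples* observations are given.
    RankDeficiencyError
        if the design matrix [1, cos(ωt), sin(ωt)] has rank < 3
        (e.g. all observations exactly half a period apart).
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and values must be 1-D and equally long")
    n = t.size
    if n < min_samples:
        raise InsufficientDataError(
            f"insufficient samples: {n} < minimum requirement of {min_samples}"
        )
    omega = 2.0 * np.pi / period_h
    X = np.column_stack([np.ones(n), np.cos(omega * t), np.sin(omega * t)])
    rank = np.linalg.matrix_rank(X)
    if rank < 3:
        raise RankDeficiencyError(
            f"cosinor design matrix rank {rank} < 3 (degenerate time points)"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    C, a, b = beta
    A = float(np.hypot(a, b))
    phi = float(np.arctan2(-b, a))
    if phi <= -np.pi:  # normalize to (−π, π]
        phi += 2.0 * np.pi
    peak_hour = float((-phi / omega) % period_h)
    fitted = X @ beta
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        r2: float | None = None
    else:
        ss_res = float(((y - fitted) ** 2).sum())
        r2 = max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return CosinorFit(
        key=None,
        target="",
        n_samples=n,
        amplitude=A,
        acrophase_rad=phi,
        peak_hour=peak_hour,
        mesor=float(C),
        r_squared=r2,
    )


def hours_since_group_origin(times: Sequence[datetime]) -> np.ndarray:
    """Hours elapsed since midnight of the group's first sampling day."""
    origin = min(times).replace(hour=0, minute=0, second=0, microsecond=0)
    return np.array([(t - origin).total_seconds() / 3600.0 for t in times])


def rhythmicity_per_infant_age(
    alpha: Sequence[AlphaResult],
    genus_rel: pd.DataFrame,
    top_genera: Sequence[str],
    samples: Sequence[SampleRecord],
    min_samples: int = MIN_SAMPLES_DEFAULT,
) -> tuple[list[CosinorFit], list[RhythmicityExclusion]]:
    """One cosinor fit per (infant, age) × (alpha metric ∪ top genus).

    Groups with fewer than *min_samples* samples are excluded with reason;
    targets are the four alpha metrics and the top-k genera (relative
    abundance). Time is hours since midnight of each group's first sampling
    day.
    """
    alpha_by_sample: dict[str, dict[str, float | None]] = {}
    for res in alpha:
        alpha_by_sample.setdefault(res.sample_id, {})[res.metric] = res.value

    groups: dict[InfantAgeKey, list[SampleRecord]] = {}
    for rec in samples:
        groups.setdefault(rec.key, []).append(rec)

    fits: list[CosinorFit] = []
    excluded: list[RhythmicityExclusion] = []
    targets = list(ALPHA_METRICS) + [g for g in top_genera]
    for key in sorted(groups):
        recs = sorted(groups[key], key=lambda r: r.collection_datetime)
        n = len(recs)
        if n < min_samples:
            excluded.append(
                RhythmicityExclusion(
                    key,
                    "all",
                    n,
                    f"minimum requirement of {min_samples} samples not met",
                )
            )
            continue
        t = hours_since_group_origin([r.collection_datetime for r in recs])
        for target in targets:
            if target in ALPHA_METRICS:
                series = [alpha_by_sample.get(r.sample_id, {}).get(target) for r in recs]
            else:
                series = [
                    float(genus_rel.at[r.sample_id, target])
                    if target in genus_rel.columns and r.sample_id in genus_rel.index
                    else None
                    for r in recs
                ]
            mask = np.array([v is not None and np.isfinite(v) for v in series])
            if mask.sum() < min_samples:
                excluded.append(
                    RhythmicityExclusion(
                        key, target, int(mask.sum()),
                        f"minimum requirement of {min_samples} samples not met",
                    )
                )
                continue
            tv = t[mask]
            yv = np.array([v for v, m in zip(series, mask) if m], dtype=float)
            try:
                fit = fit_cosinor(tv, yv, min_samples=min_samples)
            except RankDeficiencyError as exc:
                excluded.append(
                    RhythmicityExclusion(key, target, int(mask.sum()), str(exc))
                )
                continue
            fit.key = key
            fit.target = target
            fits.append(fit)
    return fits, excluded


def fits_to_frame(fits: Sequence[CosinorFit]) -> pd.DataFrame:
    rows = [
        {
            "infant_id": f.key.infant_id if f.key else "",
            "age_group": f.key.age_group if f.key else "",
            "target": f.target,
            "n_samples": f.n_samples,
            "amplitude": f.amplitude,
            "acrophase_rad": f.acrophase_rad,
            "peak_hour": f.peak_hour,
            "mesor": f.mesor,
            "r_squared": f.r_squared,
        }
        for f in fits
    ]
    return pd.DataFrame(rows)
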