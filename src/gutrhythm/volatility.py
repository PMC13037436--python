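"""Temporal volatility: median distance of an infant-age's samples to their
centroid in a 3-axis PCoA embedding of a beta-diversity matrix.

The embedding is computed once on the full cohort distance matrix by
default (``embedding_scope="cohort"``), so volatilities are comparable
across infants; per-group embeddings are available as an alternative.
If fewer than three positive eigenvalues exist, all positive axes are used
and the count is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Sequence

import numpy as np
import pandas as pd

from gutrhythm.datamodel import InfantAgeKey, SampleRecord
from gutrhythm.diversity import DistanceMatrix, pcoa
from gutrhythm.errors import GutRhythmError, IntegrityError


@dataclass
class VolatilityRecord:
    key: InfantAgeKey
    beta_metric: str
    volatility: float
    n_samples: int
    n_axes: int


@dataclass
class VolatilityExclusion:
    key: InfantAgeKey
    beta_metric: str
    n_samples: int
    reason: str


def _group_samples(
    samples: Sequence[SampleRecord],
) -> dict[InfantAgeKey, list[SampleRecord]]:
    groups: dict[InfantAgeKey, list[SampleRecord]] = {}
    for rec in samples:
        groups.setdefault(rec.key, []).append(rec)
    return groups


def compute_volatility(
    dm: DistanceMatrix,
    samples: Sequence[SampleRecord],
    n_axes: int = 3,
    embedding_scope: str = "cohort",
) -> tuple[list[VolatilityRecord], list[VolatilityExclusion]]:
    """Per infant-age: median Euclidean distance to the group centroid in the
    PCoA embedding. Groups with a single sample are reported excluded."""
    if not samples:
        raise GutRhythmError("empty metadata")
    ids_in_dm = set(dm.sample_ids)
    missing = [r.sample_id for r in samples if r.sample_id not in ids_in_dm]
    if missing:
        raise IntegrityError(
            f"samples missing from distance matrix: {sorted(missing)[:10]}"
        )
    groups = _group_samples(samples)

    records: list[VolatilityRecord] = []
    excluded: list[VolatilityExclusion] = []

    if embedding_scope == "cohort":
        emb = pcoa(dm, n_axes=n_axes, allow_fewer=True)
        for key in sorted(groups):
            sids = [r.sample_id for r in groups[key]]
            if len(sids) < 2:
                excluded.append(
                    VolatilityExclusion(key, dm.metric, len(sids), "only 1 sample")
                )
                continue
            pts = emb.coords_of(sids)
            centroid = pts.mean(axis=0)
            dists = np.linalg.norm(pts - centroid, axis=1)
            records.append(
                VolatilityRecord(
                    key, dm.metric, float(median(dists)), len(sids), pts.shape[1]
                )
            )
    elif embedding_scope == "group":
        for key in sorted(groups):
            sids = [r.sample_id for r in groups[key]]
            if len(sids) < 2:
                excluded.append(
                    VolatilityExclusion(key, dm.metric, len(sids), "only 1 sample")
                )
                continue
            sub = DistanceMatrix(sids, dm.submatrix(sids), dm.metric)
            emb = pcoa(sub, n_axes=n_axes, allow_fewer=True)
            pts = emb.coordinates
            centroid = pts.mean(axis=0)
            dists = np.linalg.norm(pts - centroid, axis=1)
            records.append(
                VolatilityRecord(
                    key, dm.metric, float(median(dists)), len(sids), pts.shape[1]
                )
            )
    else:
        raise GutRhythmError(f"unknown embedding_scope {embedding_scope!r}")
    return records, excluded


def volatility_vs_age_summary(
    records: Sequence[VolatilityRecord], samples: Sequence[SampleRecord]
) -> pd.DataFrame:
    """Join volatility with group-median age_days and sex, ready for modeling."""
    groups = _group_samples(samples)
    rows = []
    for rec in records:
        if rec.key not in groups:
            raise IntegrityError(f"volatility key {rec.key} missing from metadata")
        grp = groups[rec.key]
        rows.append(
            {
                "infant_id": rec.key.infant_id,
                "age_group": rec.key.age_group,
                "beta_metric": rec.beta_metric,
                "n_samples": rec.n_samples,
                "age_days": float(np.median([r.age_days for r in grp])),
                "sex": grp[0].sex,
                "volatility": rec.volatility,
            }
        )
    return pd.DataFrame(rows)
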