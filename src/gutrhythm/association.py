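"""Analysis-table assembly and the random-intercept mixed-model suite.

Two analysis resolutions:

- infant-age level: median-aggregated alpha diversity, cosinor R²,
  temporal volatility, CFI, BabySQUID, feeding rhythmicity, BCQ, ASQ,
  group-median age in days, sex;
- sample level: per-sample alpha diversity, stool melatonin, sleep/feeding
  history covariates, age in days, sex.

Rules applied while assembling: melatonin values strictly greater than the
cohort mean + 8·SD are excluded; per model, rows missing the outcome or the
exposure are dropped, and missing covariates are replaced by the column
median. Models are random-intercept (per infant) linear mixed models fit by
REML with Wald z inference; a failed or singular fit falls back to OLS with
the convergence flag cleared. No multiplicity correction is applied; the
suite reports the model count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from statistics import median
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from gutrhythm.actigraphy import CircadianMetrics
from gutrhythm.datamodel import (
    ALPHA_METRICS,
    BETA_METRICS,
    InfantAgeKey,
    QuestionnaireRecord,
    SampleRecord,
)
from gutrhythm.diversity import AlphaResult
from gutrhythm.errors import GutRhythmError, RankDeficiencyError
from gutrhythm.rhythmicity import CosinorFit
from gutrhythm.sleep_behavior import (
    FeedingRhythmicityRecord,
    HistoryRecord,
    SleepQualityRecord,
)
from gutrhythm.volatility import VolatilityRecord


@dataclass
class ModelSpec:
    model_id: str
    outcome: str
    exposure: str
    covariates: tuple[str, ...]
    resolution: str  # "infant_age" or "sample"
    group: str = "infant_id"

    @property
    def terms(self) -> tuple[str, ...]:
        return (self.exposure,) + self.covariates


@dataclass
class ModelFit:
    model_id: str
    outcome: str
    exposure: str
    terms: list[str]
    beta: dict[str, float]
    se: dict[str, float]
    pvalues: dict[str, float]
    re_variance: float
    resid_variance: float
    n_obs: int
    n_groups: int
    converged: bool
    n_imputed: int
    n_dropped: int


@dataclass
class ProvenanceEntry:
    stage: str
    detail: str
    count: int


def default_registry(
    rhythmicity_targets: Sequence[str],
    alpha_metrics: Sequence[str] = ALPHA_METRICS,
    beta_metrics: Sequence[str] = BETA_METRICS,
) -> list[ModelSpec]:
    """The full model suite: CFI ~ rhythmicity / diversity / volatility,
    BabySQUID ~ diversity / volatility, melatonin ~ history,
    diversity ~ history, plus volatility ~ age."""
    registry: list[ModelSpec] = []
    for target in rhythmicity_targets:
        registry.append(
            ModelSpec(
                f"eq3_{target}",
                "cfi",
                f"r2_{target}",
                ("feeding_rhythmicity", "bcq_attunement", "age_days", "sex_male"),
                "infant_age",
            )
        )
    for m in alpha_metrics:
        registry.append(
            ModelSpec(
                f"eq4_{m}",
                "cfi",
                f"alpha_{m}",
                ("bcq_attunement", "asq_composite", "age_days", "sex_male"),
                "infant_age",
            )
        )
    for m in beta_metrics:
        registry.append(
            ModelSpec(
                f"eq5_{m}",
                "cfi",
                f"vol_{m}",
                ("bcq_attunement", "asq_composite", "age_days", "sex_male"),
                "infant_age",
            )
        )
    for m in alpha_metrics:
        registry.append(
            ModelSpec(
                f"eq6_{m}",
                "babysquid",
                f"alpha_{m}",
                ("bcq_attunement", "asq_composite", "age_days", "sex_male"),
                "infant_age",
            )
        )
    for m in beta_metrics:
        registry.append(
            ModelSpec(
                f"eq7_{m}",
                "babysquid",
                f"vol_{m}",
                ("bcq_attunement", "asq_composite", "age_days", "sex_male"),
                "infant_age",
            )
        )
    registry.append(
        ModelSpec(
            "eq8_melatonin",
            "melatonin",
            "time_since_last_bowel_movement_h",
            ("prior_awake_h", "time_since_feeding_h", "age_days", "sex_male"),
            "sample",
        )
    )
    for m in alpha_metrics:
        registry.append(
            ModelSpec(
                f"eq9_{m}",
                f"alpha_{m}",
                "prior_awake_h",
                (
                    "last_sleep_duration_h",
                    "time_since_feeding_h",
                    "age_days",
                    "sex_male",
                ),
                "sample",
            )
        )
    for m in beta_metrics:
        registry.append(
            ModelSpec(
                f"volage_{m}",
                f"vol_{m}",
                "age_days",
                ("sex_male",),
                "infant_age",
            )
        )
    return registry


# ---------------------------------------------------------------------------
# analysis-table assembly


def build_analysis_tables(
    samples: Sequence[SampleRecord],
    alpha: Sequence[AlphaResult],
    rhythmicity_fits: Sequence[CosinorFit] = (),
    volatility_records: Sequence[VolatilityRecord] = (),
    circadian: Sequence[CircadianMetrics] = (),
    squid: Sequence[SleepQualityRecord] = (),
    feeding: Sequence[FeedingRhythmicityRecord] = (),
    questionnaires: Sequence[QuestionnaireRecord] = (),
    history: Sequence[HistoryRecord] = (),
    melatonin_outlier_sd: float = 8.0,
) -> tuple[pd.DataFrame, pd.DataFrame, list[ProvenanceEntry]]:
    """Assemble the infant-age and sample analysis tables."""
    provenance: list[ProvenanceEntry] = []

    alpha_by_sample: dict[str, dict[str, float]] = {}
    for res in alpha:
        if res.value is not None:
            alpha_by_sample.setdefault(res.sample_id, {})[res.metric] = res.value

    groups: dict[InfantAgeKey, list[SampleRecord]] = {}
    for rec in samples:
        groups.setdefault(rec.key, []).append(rec)

    # ---- sample-level table
    hist_by_sample = {h.sample_id: h for h in history}
    mel_values = np.array(
        [r.melatonin_pg_per_g for r in samples if r.melatonin_pg_per_g is not None]
    )
    mel_cut = np.inf
    if mel_values.size >= 2:
        mel_cut = mel_values.mean() + melatonin_outlier_sd * mel_values.std(ddof=1)
    sample_rows = []
    n_mel_excluded = 0
    for rec in sorted(samples, key=lambda r: r.sample_id):
        mel = rec.melatonin_pg_per_g
        if mel is not None and mel > mel_cut:
            n_mel_excluded += 1
            provenance.append(
                ProvenanceEntry(
                    "melatonin_outlier",
                    f"{rec.sample_id}: {mel} > mean + {melatonin_outlier_sd}·SD",
                    1,
                )
            )
            mel = None
        h = hist_by_sample.get(rec.sample_id)
        row = {
            "sample_id": rec.sample_id,
            "infant_id": rec.infant_id,
            "age_group": rec.age_group,
            "age_days": float(rec.age_days),
            "sex_male": 1.0 if rec.sex == "male" else 0.0,
            "melatonin": mel,
            "prior_awake_h": h.prior_awake_h if h else None,
            "last_sleep_duration_h": h.last_sleep_duration_h if h else None,
            "time_since_feeding_h": h.time_since_feeding_h if h else None,
            "time_since_last_bowel_movement_h": (
                h.time_since_last_bowel_movement_h if h else None
            ),
        }
        for m in ALPHA_METRICS:
            row[f"alpha_{m}"] = alpha_by_sample.get(rec.sample_id, {}).get(m)
        sample_rows.append(row)
    sample_table = pd.DataFrame(sample_rows)

    # ---- infant-age table
    r2_by_key: dict[InfantAgeKey, dict[str, float | None]] = {}
    for fit in rhythmicity_fits:
        r2_by_key.setdefault(fit.key, {})[fit.target] = fit.r_squared
    vol_by_key: dict[InfantAgeKey, dict[str, float]] = {}
    for vr in volatility_records:
        vol_by_key.setdefault(vr.key, {})[vr.beta_metric] = vr.volatility
    cfi_by_key = {c.key: c.CFI for c in circadian}
    squid_by_key = {s.key: s.babysquid for s in squid}
    feed_by_key = {f.key: f.value for f in feeding}
    q_by_key = {q.key: q for q in questionnaires}

    keys = sorted(
        set(groups)
        | set(r2_by_key)
        | set(vol_by_key)
        | set(cfi_by_key)
        | set(squid_by_key)
    )
    rhythm_targets = sorted({f.target for f in rhythmicity_fits})
    ia_rows = []
    for key in keys:
        grp = groups.get(key, [])
        q = q_by_key.get(key)
        row: dict = {
            "infant_id": key.infant_id,
            "age_group": key.age_group,
            "age_days": float(np.median([r.age_days for r in grp])) if grp else None,
            "sex_male": (1.0 if grp[0].sex == "male" else 0.0) if grp else None,
            "n_samples": len(grp),
            "cfi": cfi_by_key.get(key),
            "babysquid": squid_by_key.get(key),
            "feeding_rhythmicity": feed_by_key.get(key),
            "bcq_attunement": q.bcq_attunement if q else None,
            "asq_composite": q.asq_composite if q else None,
        }
        for m in ALPHA_METRICS:
            vals = [
                alpha_by_sample[r.sample_id][m]
                for r in grp
                if r.sample_id in alpha_by_sample
                and m in alpha_by_sample[r.sample_id]
            ]
            row[f"alpha_{m}"] = float(median(vals)) if vals else None
        for target in rhythm_targets:
            row[f"r2_{target}"] = r2_by_key.get(key, {}).get(target)
        for m in BETA_METRICS:
            row[f"vol_{m}"] = vol_by_key.get(key, {}).get(m)
        ia_rows.append(row)
    infant_age_table = pd.DataFrame(ia_rows)
    provenance.append(
        ProvenanceEntry("melatonin_outlier", "total excluded", n_mel_excluded)
    )
    provenance.append(
        ProvenanceEntry("tables", "infant_age rows", len(infant_age_table))
    )
    provenance.append(ProvenanceEntry("tables", "sample rows", len(sample_table)))
    return infant_age_table, sample_table, provenance


# ---------------------------------------------------------------------------
# model fitting


def _prepare_design(
    spec: ModelSpec, table: pd.DataFrame
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray, int, int]:
    """Drop rows missing outcome/exposure, median-impute covariates.

    Returns (y, X with intercept, groups, n_imputed, n_dropped).
    """
    needed = [spec.outcome, spec.exposure, *spec.covariates, spec.group]
    missing_cols = [c for c in needed if c not in table.columns]
    if missing_cols:
        raise GutRhythmError(
            f"model {spec.model_id}: columns not in table: {missing_cols}"
        )
    df = table[needed].copy()
    for c in (spec.outcome, spec.exposure, *spec.covariates):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    keep = df[spec.outcome].notna() & df[spec.exposure].notna()
    n_dropped = int((~keep).sum())
    df = df[keep]
    n_imputed = 0
    for c in spec.covariates:
        na = df[c].isna()
        if na.any():
            if df[c].notna().sum() == 0:
                raise GutRhythmError(
                    f"model {spec.model_id}: covariate {c} entirely missing"
                )
            df.loc[na, c] = float(df[c].median())
            n_imputed += int(na.sum())
    if len(df) == 0:
        raise GutRhythmError(f"model {spec.model_id}: empty table after exclusions")
    y = df[spec.outcome].to_numpy(dtype=float)
    X = pd.DataFrame({"intercept": np.ones(len(df))})
    for c in spec.terms:
        X[c] = df[c].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name offending columns via incremental rank checks
        collinear = []
        cols: list[str] = []
        for c in X.columns:
            trial = X[cols + [c]].to_numpy()
            if np.linalg.matrix_rank(trial) == len(cols):
                collinear.append(c)
            else:
                cols.append(c)
        raise RankDeficiencyError(
            f"model {spec.model_id}: collinear terms {collinear}"
        )
    return y, X, df[spec.group].to_numpy(), n_imputed, n_dropped


def fit_lmm(spec: ModelSpec, table: pd.DataFrame, reml: bool = True) -> ModelFit:
    """Random-intercept LMM (REML, Wald z); OLS fallback on singular fits."""
    y, X, groups, n_imputed, n_dropped = _prepare_design(spec, table)
    n_groups = len(np.unique(groups))
    if len(y) < X.shape[1] + 1:
        raise GutRhythmError(
            f"model {spec.model_id}: {len(y)} observations for {X.shape[1]} terms"
        )
    if n_groups < 2:
        raise GutRhythmError(f"model {spec.model_id}: fewer than 2 infants")
    converged = False
    result = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, X.to_numpy(), groups=groups)
            result = model.fit(reml=reml, method=["lbfgs", "powell"])
        ok = (
            bool(getattr(result, "converged", False))
            and np.all(np.isfinite(result.params))
            and np.all(np.isfinite(np.asarray(result.bse)[: X.shape[1]]))
        )
        if ok:
            converged = True
    except (np.linalg.LinAlgError, ValueError):
        result = None

    names = list(X.columns)
    if converged and result is not None:
        params = np.asarray(result.params)[: len(names)]
        bse = np.asarray(result.bse)[: len(names)]
        pvals = np.asarray(result.pvalues)[: len(names)]
        re_var = float(np.asarray(result.cov_re).ravel()[0])
        resid_var = float(result.scale)
    else:
        # singular/failed random-effect fit: ordinary least squares
        ols = sm.OLS(y, X.to_numpy()).fit()
        params = np.asarray(ols.params)
        bse = np.asarray(ols.bse)
        from scipy.stats import norm

        pvals = 2 * norm.sf(np.abs(params / bse))
        re_var = 0.0
        resid_var = float(ols.scale)
    return ModelFit(
        model_id=spec.model_id,
        outcome=spec.outcome,
        exposure=spec.exposure,
        terms=names,
        beta={n: float(b) for n, b in zip(names, params)},
        se={n: float(s) for n, s in zip(names, bse)},
        pvalues={n: float(p) for n, p in zip(names, pvals)},
        re_variance=re_var,
        resid_variance=resid_var,
        n_obs=len(y),
        n_groups=n_groups,
        converged=converged,
        n_imputed=n_imputed,
        n_dropped=n_dropped,
    )


def run_model_suite(
    registry: Sequence[ModelSpec],
    infant_age_table: pd.DataFrame,
    sample_table: pd.DataFrame,
    reml: bool = True,
) -> tuple[list[ModelFit], pd.DataFrame, list[str]]:
    """Fit every registered model; per-model failures are recorded and the
    suite continues. Returns (fits, summary table, failure messages)."""
    fits: list[ModelFit] = []
    failures: list[str] = []
    for spec in registry:
        table = infant_age_table if spec.resolution == "infant_age" else sample_table
        try:
            fits.append(fit_lmm(spec, table, reml=reml))
        except GutRhythmError as exc:
            failures.append(f"{spec.model_id}: {exc}")
    rows = []
    for f in fits:
        for term in f.terms:
            rows.append(
                {
                    "model_id": f.model_id,
                    "outcome": f.outcome,
                    "exposure": f.exposure,
                    "term": term,
                    "beta": f.beta[term],
                    "se": f.se[term],
                    "p_value": f.pvalues[term],
                    "n_obs": f.n_obs,
                    "n_infants": f.n_groups,
                    "converged": int(f.converged),
                    "n_models_in_suite": len(registry),
                }
            )
    return fits, pd.DataFrame(rows), failures
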