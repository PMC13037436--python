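"""Synthetic cohort generator.

Produces a full input bundle — feature table with diurnally modulated
genera, taxonomy, random phylogeny, sample metadata with clock times,
actimetry, 15-min diaries with feeds, questionnaires, stool melatonin —
together with a ground-truth record sufficient to score parameter recovery
for every downstream stage.

Generative model for counts: per sample collected at clock time *t*, each
genus gets a log intensity ``baseline + A_g·cos(2π(t − φ_g)/24) +
infant effect + noise``; intensities are split over the genus's ASVs with
fixed weights, gated by an age-dependent acquisition process (so
detectable richness grows with age at the configured slope), and counts are
drawn multinomially at the sample's library size. Diurnal modulation thus
acts on log relative abundance *before* multinomial sampling, keeping
counts integral and depth-controlled.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, time, timedelta
from typing import Sequence

import numpy as np
from skbio import TreeNode

from gutrhythm.config import SyntheticCohortConfig
from gutrhythm.datamodel import (
    ActivitySeries,
    DiaryTimeline,
    FeatureTable,
    InfantAgeKey,
    QuestionnaireRecord,
    RootedTree,
    SampleRecord,
    TaxonomyMap,
)
from gutrhythm.errors import ConfigError
from gutrhythm.io import CohortBundle, write_cohort_bundle

_EPOCH_DATE = date(2024, 1, 1)


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


def _at_hours(start: datetime, hours: float) -> datetime:
    """start + hours, truncated to whole seconds (the on-disk resolution)."""
    return (start + timedelta(hours=float(hours))).replace(microsecond=0)


def _window_start(infant_idx: int, age_group: int) -> datetime:
    day = _EPOCH_DATE + timedelta(days=infant_idx * 7 + age_group * 30)
    return datetime.combine(day, time(0, 0))


@dataclass
class CohortLayout:
    """Deterministic per-infant structure shared by all three simulators."""

    infant_ids: list[str]
    sex: dict[str, str]
    age_days: dict[InfantAgeKey, int]
    n_samples: dict[InfantAgeKey, int]


def _build_layout(cfg: SyntheticCohortConfig, rng: np.random.Generator) -> CohortLayout:
    infant_ids = [f"I{i + 1:02d}" for i in range(cfg.n_infants)]
    sex = {
        iid: ("female" if rng.random() < cfg.sex_female_ratio else "male")
        for iid in infant_ids
    }
    age_days: dict[InfantAgeKey, int] = {}
    n_samples: dict[InfantAgeKey, int] = {}
    # 1 + Binomial(10, 0.3) has median 4 and support [1, 11]
    p_extra = (cfg.samples_median - 1) / 10.0
    for iid in infant_ids:
        days = []
        for spec in cfg.age_groups:
            d = int(round(rng.normal(spec.age_days_mean, spec.age_days_sd)))
            days.append(max(1, d))
        days = sorted(days)  # keep age_days consistent with age_group ordering
        for spec, d in zip(cfg.age_groups, days):
            key = InfantAgeKey(iid, spec.age_group)
            age_days[key] = d
            n = 1 + int(rng.binomial(10, p_extra))
            n_samples[key] = int(min(max(n, 1), cfg.samples_max))
    return CohortLayout(infant_ids, sex, age_days, n_samples)


# ---------------------------------------------------------------------------
# feature table


def _random_tree(feature_ids: Sequence[str], rng: np.random.Generator) -> RootedTree:
    """Random coalescent-style merging with exponential branch lengths."""
    lineages = [TreeNode(name=f, length=float(rng.exponential(0.1))) for f in feature_ids]
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        b = lineages.pop(j)
        a = lineages.pop(i)
        parent = TreeNode(length=float(rng.exponential(0.1)), children=[a, b])
        lineages.append(parent)
    root = lineages[0]
    root.length = None
    return RootedTree(root)


def simulate_feature_table(
    cfg: SyntheticCohortConfig, seed: int, layout: CohortLayout | None = None
) -> tuple[FeatureTable, TaxonomyMap, RootedTree, list[SampleRecord], dict]:
    cfg.validate()
    rng = _rng(seed, 1)
    if layout is None:
        layout = _build_layout(cfg, _rng(seed, 0))

    # ASV roster
    asv_genus: list[int] = []
    asv_weight: list[float] = []
    for g, spec in enumerate(cfg.genera):
        w = rng.dirichlet(np.ones(spec.n_asvs) * 2.0)
        for k in range(spec.n_asvs):
            asv_genus.append(g)
            asv_weight.append(float(w[k]))
    n_core = len(asv_genus)
    feature_ids = [f"ASV{k + 1:04d}" for k in range(n_core + cfg.n_rare_features)]
    core_ids = feature_ids[:n_core]
    rare_ids = feature_ids[n_core:]

    unassigned = rng.random(n_core + cfg.n_rare_features) < cfg.phylum_unassigned_fraction

    taxonomy = {}
    for k, fid in enumerate(core_ids):
        spec = cfg.genera[asv_genus[k]]
        if unassigned[k]:
            taxonomy[fid] = ["Bacteria", "", "", "", "", ""]
        else:
            taxonomy[fid] = [
                "Bacteria",
                spec.phylum,
                "",
                "",
                spec.family,
                spec.name,
            ]
    for k, fid in enumerate(rare_ids):
        if unassigned[n_core + k]:
            taxonomy[fid] = ["Bacteria", "", "", "", "", ""]
        else:
            taxonomy[fid] = ["Bacteria", "Firmicutes", "", "", "", ""]

    # age-dependent acquisition gating
    gated = rng.random(n_core) > cfg.baseline_present_fraction
    n_gated = int(gated.sum())
    horizon = max(n_gated / cfg.richness_age_slope, 1.0) if n_gated else 1.0
    acquisition_day = np.zeros((cfg.n_infants, n_core))
    for i in range(cfg.n_infants):
        acquisition_day[i, gated] = rng.uniform(0, horizon, size=n_gated)

    infant_effect = rng.normal(0, cfg.infant_effect_sd, size=(cfg.n_infants, len(cfg.genera)))

    amplitudes = np.array([g.amplitude for g in cfg.genera])
    acrophases = np.array([g.acrophase_h for g in cfg.genera])
    baselines = np.array([g.baseline_log for g in cfg.genera])

    samples: list[SampleRecord] = []
    rows: list[np.ndarray] = []
    sample_ids: list[str] = []
    counter = 0
    for i, iid in enumerate(layout.infant_ids):
        for spec_ag in cfg.age_groups:
            key = InfantAgeKey(iid, spec_ag.age_group)
            n = layout.n_samples[key]
            start = _window_start(i, spec_ag.age_group)
            if spec_ag.age_group >= 6:
                # morning-weighted mixture at the oldest age
                offs = np.where(
                    rng.random(n) < 0.5,
                    rng.uniform(0, cfg.window_h, size=n),
                    rng.integers(0, 2, size=n) * 24.0
                    + np.clip(rng.normal(12.0, 2.5, size=n), 0.0, 23.99),
                )
            else:
                offs = rng.uniform(0, cfg.window_h, size=n)
            offs = np.sort(offs)
            for t in offs:
                counter += 1
                sid = f"S{counter:04d}"
                clock = t % 24.0
                log_g = (
                    baselines
                    + amplitudes * np.cos(2 * np.pi * (clock - acrophases) / 24.0)
                    + infant_effect[i]
                    + rng.normal(0, cfg.log_noise_sd, size=len(cfg.genera))
                )
                intensity = np.exp(log_g)
                asv_int = np.array(
                    [intensity[asv_genus[k]] * asv_weight[k] for k in range(n_core)]
                )
                present = acquisition_day[i] <= layout.age_days[key]
                asv_int = asv_int * present
                if asv_int.sum() <= 0:
                    asv_int = np.ones(n_core)
                probs = asv_int / asv_int.sum()
                lib = int(
                    round(np.exp(rng.normal(cfg.library_size_log_mean, cfg.library_size_log_sd)))
                )
                lib = max(lib, cfg.library_size_min)
                if lib <= 0:
                    raise ConfigError("library size must be positive")
                counts = rng.multinomial(lib, probs)
                rows.append(counts)
                sample_ids.append(sid)
                samples.append(
                    SampleRecord(
                        sample_id=sid,
                        infant_id=iid,
                        age_group=spec_ag.age_group,
                        age_days=layout.age_days[key],
                        collection_datetime=_at_hours(start, t),
                        sex=layout.sex[iid],
                    )
                )
    X = np.zeros((len(rows), n_core + cfg.n_rare_features), dtype=np.int64)
    X[:, :n_core] = np.stack(rows)
    # plant rare features: total count in [1, 9] spread over random samples
    for k in range(cfg.n_rare_features):
        total = int(rng.integers(1, 10))
        idx = rng.integers(0, len(rows), size=total)
        for s in idx:
            X[s, n_core + k] += 1

    table = FeatureTable(sample_ids, feature_ids, X)
    tree = _random_tree(feature_ids, rng)
    ground_truth = {
        "genera": [
            {
                "name": g.name,
                "baseline_log": g.baseline_log,
                "amplitude": g.amplitude,
                "acrophase_h": g.acrophase_h,
            }
            for g in cfg.genera
        ],
        "top_genera_by_baseline": [
            g.name
            for g in sorted(cfg.genera, key=lambda s: -s.baseline_log)[:5]
        ],
        "phylum_unassigned_features": [
            fid for fid, u in zip(feature_ids, unassigned) if u
        ],
        "rare_features": list(rare_ids),
        "richness_age_slope": cfg.richness_age_slope,
        "n_samples": {
            f"{k.infant_id}:{k.age_group}": layout.n_samples[k]
            for k in sorted(layout.n_samples)
        },
        "age_days": {
            f"{k.infant_id}:{k.age_group}": layout.age_days[k]
            for k in sorted(layout.age_days)
        },
        "sex": dict(sorted(layout.sex.items())),
    }
    return table, TaxonomyMap(taxonomy), tree, samples, ground_truth


# ---------------------------------------------------------------------------
# actimetry


def _day_profile(clock_h: np.ndarray, mesor: float, ra: float, peak: float) -> np.ndarray:
    """Rectified-sinusoid day shape: zero trough for 12 h when ra = 1."""
    base = 2.0 * np.maximum(0.0, np.cos(2 * np.pi * (clock_h - peak) / 24.0))
    return mesor * ((1.0 - ra) + ra * base)


def simulate_actigraphy(
    cfg: SyntheticCohortConfig,
    seed: int,
    layout: CohortLayout | None = None,
    epoch_minutes: int = 1,
) -> tuple[dict[InfantAgeKey, ActivitySeries], dict]:
    cfg.validate()
    if 60 % epoch_minutes != 0:
        raise ConfigError("epoch length must divide 60 minutes")
    rng = _rng(seed, 2)
    if layout is None:
        layout = _build_layout(cfg, _rng(seed, 0))
    series: dict[InfantAgeKey, ActivitySeries] = {}
    truth: dict[str, dict] = {}
    per_day = 1440 // epoch_minutes
    for i, iid in enumerate(layout.infant_ids):
        for spec_ag in cfg.age_groups:
            key = InfantAgeKey(iid, spec_ag.age_group)
            n_days = int(round(rng.normal(cfg.days_mean, 2.71)))
            n_days = int(min(max(n_days, cfg.days_min), cfg.days_max))
            start = _window_start(i, spec_ag.age_group)
            n_epochs = n_days * per_day
            t_h = np.arange(n_epochs) * epoch_minutes / 60.0
            clock = t_h % 24.0
            profile = _day_profile(clock, cfg.activity_mesor, cfg.relative_amplitude, cfg.peak_hour)
            anti = _day_profile(
                (clock + 12.0) % 24.0, cfg.activity_mesor, cfg.relative_amplitude, cfg.peak_hour
            )
            if cfg.fragmentation_per_h > 0:
                p_flip = cfg.fragmentation_per_h * epoch_minutes / 60.0
                flips = rng.random(n_epochs) < p_flip
                state = np.cumsum(flips) % 2 == 1
            else:
                state = np.zeros(n_epochs, dtype=bool)
            activity = np.where(state, anti, profile)
            if cfg.activity_noise_sd > 0:
                activity = activity + rng.normal(0, cfg.activity_noise_sd, n_epochs)
            activity = np.maximum(activity, 0.0)
            wear = np.ones(n_epochs, dtype=bool)
            if cfg.nonwear_fraction > 0:
                block = 2 * 60 // epoch_minutes  # ~2-h non-wear blocks
                n_blocks = int(cfg.nonwear_fraction * n_epochs / block)
                for _ in range(n_blocks):
                    s = int(rng.integers(0, max(n_epochs - block, 1)))
                    wear[s : s + block] = False
            series[key] = ActivitySeries(
                key=key,
                epoch_start=[
                    start + timedelta(minutes=e * epoch_minutes) for e in range(n_epochs)
                ],
                activity=activity,
                wear=wear,
                epoch_minutes=epoch_minutes,
            )
            truth[f"{iid}:{spec_ag.age_group}"] = {
                "n_days": n_days,
                "relative_amplitude": cfg.relative_amplitude,
                "fragmentation_per_h": cfg.fragmentation_per_h,
                "peak_hour": cfg.peak_hour,
                "mesor": cfg.activity_mesor,
            }
    return series, {"actigraphy": truth}


# ---------------------------------------------------------------------------
# diaries, questionnaires, melatonin


def simulate_diary_and_questionnaires(
    cfg: SyntheticCohortConfig,
    seed: int,
    layout: CohortLayout | None = None,
    samples: Sequence[SampleRecord] | None = None,
) -> tuple[dict[InfantAgeKey, DiaryTimeline], list[QuestionnaireRecord], dict]:
    """Diaries over each 48-h window (sleep/wake from the activity ground
    truth discretized to 15-min intervals, feeds at the configured cadence),
    questionnaire records with age trends, and melatonin values written onto
    *samples* in place."""
    cfg.validate()
    rng = _rng(seed, 3)
    if layout is None:
        layout = _build_layout(cfg, _rng(seed, 0))
    diaries: dict[InfantAgeKey, DiaryTimeline] = {}
    questionnaires: list[QuestionnaireRecord] = []
    for i, iid in enumerate(layout.infant_ids):
        for spec_ag in cfg.age_groups:
            key = InfantAgeKey(iid, spec_ag.age_group)
            start = _window_start(i, spec_ag.age_group)
            n_iv = int(cfg.window_h * 60 / 15)
            interval_start = [start + timedelta(minutes=15 * k) for k in range(n_iv)]
            mid_h = np.array([15 * k / 60.0 + 0.125 for k in range(n_iv)])
            if cfg.diary_jitter_min > 0:
                mid_h = mid_h + rng.normal(0, cfg.diary_jitter_min / 60.0, n_iv)
            clock = mid_h % 24.0
            # sleep = the trough half of the activity profile
            is_sleep = np.cos(2 * np.pi * (clock - cfg.peak_hour) / 24.0) < 0.0
            feeds: list[datetime] = []
            t = 7.0 + (rng.uniform(-0.5, 0.5) if cfg.feed_interval_jitter_h > 0 else 0.0)
            while t < cfg.window_h:
                feeds.append(_at_hours(start, t))
                step = cfg.feed_interval_mean_h
                if cfg.feed_interval_jitter_h > 0:
                    step = max(0.25, step + rng.normal(0, cfg.feed_interval_jitter_h))
                t += step
            diaries[key] = DiaryTimeline(
                key=key,
                interval_start=interval_start,
                is_sleep=is_sleep,
                feed_times=feeds,
            )
            age = layout.age_days[key]
            def _miss(v: float) -> float | None:
                return None if rng.random() < cfg.bisq_missing_fraction else v
            questionnaires.append(
                QuestionnaireRecord(
                    infant_id=iid,
                    age_group=spec_ag.age_group,
                    bisq_night_sleep_h=_miss(
                        max(
                            2.0,
                            cfg.bisq_night_sleep_base_h
                            + cfg.bisq_night_sleep_slope_per_day * age
                            + rng.normal(0, cfg.bisq_noise_sd),
                        )
                    ),
                    bisq_latency_h=_miss(
                        max(
                            0.05,
                            cfg.bisq_latency_base_h
                            + cfg.bisq_latency_slope_per_day * age
                            + rng.normal(0, cfg.bisq_noise_sd / 3),
                        )
                    ),
                    bisq_bedtime_clock_h=_miss(
                        float(
                            np.clip(
                                cfg.bisq_bedtime_base_h + rng.normal(0, cfg.bisq_noise_sd),
                                18.0,
                                23.9,
                            )
                        )
                    ),
                    bisq_n_awakenings=_miss(
                        max(
                            0.0,
                            cfg.bisq_awakenings_base
                            + cfg.bisq_awakenings_slope_per_day * age
                            + rng.normal(0, cfg.bisq_noise_sd),
                        )
                    ),
                    bcq_attunement=float(rng.normal(cfg.bcq_mean, cfg.bcq_sd)),
                    asq_composite=float(rng.normal(cfg.asq_mean, cfg.asq_sd)),
                )
            )
    if samples is not None:
        for rec in samples:
            rec.melatonin_pg_per_g = float(
                cfg.melatonin_intercept
                + cfg.melatonin_age_slope * rec.age_days
                + rng.lognormal(0.0, cfg.melatonin_noise_sigma)
            )
    truth = {
        "melatonin_intercept": cfg.melatonin_intercept,
        "melatonin_age_slope": cfg.melatonin_age_slope,
        "feed_interval_mean_h": cfg.feed_interval_mean_h,
        "feed_interval_jitter_h": cfg.feed_interval_jitter_h,
        "bisq_slopes": {
            "night_sleep_per_day": cfg.bisq_night_sleep_slope_per_day,
            "latency_per_day": cfg.bisq_latency_slope_per_day,
            "awakenings_per_day": cfg.bisq_awakenings_slope_per_day,
        },
    }
    return diaries, questionnaires, truth


# ---------------------------------------------------------------------------
# orchestration


def generate_cohort(
    cfg: SyntheticCohortConfig, seed: int, out_dir: str | None = None
) -> CohortBundle:
    """Run all three simulators with derived sub-seeds and assemble a bundle."""
    cfg.validate()
    layout = _build_layout(cfg, _rng(seed, 0))
    table, taxonomy, tree, samples, truth_table = simulate_feature_table(
        cfg, seed, layout
    )
    actimetry, truth_act = simulate_actigraphy(cfg, seed, layout)
    diaries, questionnaires, truth_diary = simulate_diary_and_questionnaires(
        cfg, seed, layout, samples
    )
    ground_truth = {**truth_table, **truth_act, **truth_diary, "seed": int(seed)}
    bundle = CohortBundle(
        table=table,
        taxonomy=taxonomy,
        tree=tree,
        samples=samples,
        questionnaires=questionnaires,
        actimetry=actimetry,
        diaries=diaries,
        ground_truth=ground_truth,
    )
    if out_dir is not None:
        write_cohort_bundle(bundle, out_dir)
    return bundle
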