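"""Stage orchestration: filter → diversity → {rhythmicity, volatility} and
actigraphy/diary stages → association.

Each stage writes its outputs (TSV) before the next consumes them, and the
whole run is a pure function of (inputs, config, seed): repeated runs with
the same config and seed produce byte-identical outputs.
"""

from __future__ import annotations

import logging
import os

import pandas as pd

from gutrhythm import actigraphy as actig
from gutrhythm import association as assoc
from gutrhythm import diversity as div
from gutrhythm import rhythmicity as rhythm
from gutrhythm import sleep_behavior as sleep
from gutrhythm import volatility as vol
from gutrhythm.config import Config, dump_config
from gutrhythm.errors import GutRhythmError, InsufficientDataError, StageError
from gutrhythm.io import (
    CohortBundle,
    load_cohort_bundle,
    write_feature_table,
    write_long_table,
    write_samples,
)
from gutrhythm.simulate import generate_cohort

logger = logging.getLogger("gutrhythm")


def _write_df(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="")


def write_distance_matrix(dm: div.DistanceMatrix, path: str) -> None:
    df = pd.DataFrame(dm.data, index=dm.sample_ids, columns=dm.sample_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_distance_matrix(path: str, metric: str) -> div.DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return div.DistanceMatrix(list(df.index), df.to_numpy(dtype=float), metric)


def read_alpha_results(path: str) -> list[div.AlphaResult]:
    df = pd.read_csv(path, sep="\t")
    return [
        div.AlphaResult(
            str(r["sample_id"]),
            str(r["metric"]),
            None if pd.isna(r["value"]) else float(r["value"]),
        )
        for _, r in df.iterrows()
    ]


def stage_filter(cfg: Config, bundle: CohortBundle, out_dir: str):
    table, report = div.filter_table(
        bundle.table,
        bundle.taxonomy,
        min_feature_total=cfg.filter.min_feature_total,
        min_depth=cfg.filter.min_depth,
        order=cfg.filter.order,
    )
    retained = set(table.sample_ids)
    samples = [r for r in bundle.samples if r.sample_id in retained]
    write_feature_table(table, os.path.join(out_dir, "filtered_table.tsv"))
    write_long_table(
        report,
        os.path.join(out_dir, "filter_exclusions.tsv"),
        columns=["entity", "entity_id", "reason"],
    )
    write_samples(samples, os.path.join(out_dir, "samples_retained.tsv"))
    logger.info(
        "filter: %d features × %d samples retained, %d exclusions",
        table.n_features,
        table.n_samples,
        len(report),
    )
    return table, samples


def stage_diversity(cfg: Config, table, tree, taxonomy, out_dir: str):
    alpha = div.bootstrapped_alpha(
        table, tree, depth=cfg.diversity.depth, n_boot=cfg.diversity.n_boot,
        seed=cfg.seed,
    )
    write_long_table(
        alpha,
        os.path.join(out_dir, "alpha.tsv"),
        columns=["sample_id", "metric", "value"],
    )
    dms = div.bootstrapped_beta(
        table,
        tree,
        depth=cfg.diversity.depth,
        n_boot=cfg.diversity.n_boot,
        seed=cfg.seed,
        weighted_normalized=cfg.diversity.weighted_unifrac_normalized,
    )
    for m, dm in dms.items():
        write_distance_matrix(dm, os.path.join(out_dir, f"beta_{m}.tsv"))
    genus_rel, top = div.collapse_to_genus(
        table, taxonomy, top_k=cfg.diversity.top_k_genera
    )
    out = genus_rel.copy()
    out.index.name = "sample_id"
    out.to_csv(os.path.join(out_dir, "genus_relative_abundance.tsv"), sep="\t")
    with open(os.path.join(out_dir, "top_genera.txt"), "w") as fh:
        fh.write("\n".join(top) + "\n")
    logger.info("diversity: %d alpha rows, top genera %s", len(alpha), top)
    return alpha, dms, genus_rel, top


def stage_rhythmicity(cfg: Config, alpha, genus_rel, top, samples, out_dir: str):
    fits, excluded = rhythm.rhythmicity_per_infant_age(
        alpha, genus_rel, top, samples, min_samples=cfg.rhythmicity.min_samples
    )
    _write_df(rhythm.fits_to_frame(fits), os.path.join(out_dir, "rhythmicity.tsv"))
    write_long_table(
        excluded,
        os.path.join(out_dir, "rhythmicity_exclusions.tsv"),
        columns=["infant_id", "age_group", "target", "n_samples", "reason"],
    )
    logger.info("rhythmicity: %d fits, %d exclusions", len(fits), len(excluded))
    return fits


def stage_volatility(cfg: Config, dms, samples, out_dir: str):
    records: list[vol.VolatilityRecord] = []
    exclusions = []
    for m, dm in dms.items():
        recs, excl = vol.compute_volatility(
            dm,
            samples,
            n_axes=cfg.volatility.n_axes,
            embedding_scope=cfg.volatility.embedding_scope,
        )
        records.extend(recs)
        exclusions.extend(excl)
    write_long_table(
        records,
        os.path.join(out_dir, "volatility.tsv"),
        columns=["infant_id", "age_group", "beta_metric", "volatility", "n_samples", "n_axes"],
    )
    write_long_table(
        exclusions,
        os.path.join(out_dir, "volatility_exclusions.tsv"),
        columns=["infant_id", "age_group", "beta_metric", "n_samples", "reason"],
    )
    summary = vol.volatility_vs_age_summary(records, samples)
    _write_df(summary, os.path.join(out_dir, "volatility_vs_age.tsv"))
    logger.info("volatility: %d records", len(records))
    return records


def stage_actigraphy(cfg: Config, actimetry, out_dir: str):
    metrics: list[actig.CircadianMetrics] = []
    skipped = []
    for key in sorted(actimetry):
        try:
            metrics.append(
                actig.circadian_function_index(
                    actimetry[key],
                    min_wear_fraction=cfg.actigraphy.min_wear_fraction,
                    min_days=cfg.actigraphy.min_days,
                )
            )
        except InsufficientDataError as exc:
            skipped.append(
                {"infant_id": key.infant_id, "age_group": key.age_group, "reason": str(exc)}
            )
    write_long_table(
        metrics,
        os.path.join(out_dir, "circadian.tsv"),
        columns=[
            "infant_id", "age_group", "n_days", "n_hour_bins",
            "IS", "IV_raw", "IV", "M10", "L5", "RA", "CFI", "note",
        ],
    )
    write_long_table(
        skipped,
        os.path.join(out_dir, "circadian_exclusions.tsv"),
        columns=["infant_id", "age_group", "reason"],
    )
    logger.info("actigraphy: %d CFIs, %d skipped", len(metrics), len(skipped))
    return metrics


def stage_squid(cfg: Config, questionnaires, out_dir: str):
    records, excl = sleep.compute_babysquid(
        questionnaires,
        max_missing=cfg.squid.max_missing,
        max_night_sleep_h=cfg.squid.max_night_sleep_h,
        max_latency_h=cfg.squid.max_latency_h,
    )
    write_long_table(
        records,
        os.path.join(out_dir, "babysquid.tsv"),
        columns=[
            "infant_id", "age_group", "duration_scaled", "latency_rev",
            "bedtime_rev", "awakenings_rev", "babysquid", "n_imputed",
        ],
    )
    write_long_table(
        excl,
        os.path.join(out_dir, "babysquid_exclusions.tsv"),
        columns=["infant_id", "age_group", "n_missing", "reason"],
    )
    logger.info("squid: %d records, %d excluded", len(records), len(excl))
    return records


def stage_history(cfg: Config, samples, diaries, out_dir: str):
    history = sleep.derive_sample_history(samples, diaries)
    write_long_table(
        history,
        os.path.join(out_dir, "history.tsv"),
        columns=[
            "sample_id", "prior_awake_h", "last_sleep_duration_h",
            "time_since_feeding_h", "time_since_last_bowel_movement_h",
        ],
    )
    feeding = sleep.feeding_rhythmicity(diaries, aggregation=cfg.squid.day_sd_aggregation)
    write_long_table(
        feeding,
        os.path.join(out_dir, "feeding_rhythmicity.tsv"),
        columns=["infant_id", "age_group", "value", "n_days", "n_days_skipped"],
    )
    logger.info("history: %d sample records, %d feeding records", len(history), len(feeding))
    return history, feeding


def stage_associate(
    cfg: Config,
    samples,
    alpha,
    fits,
    volatility_records,
    circadian,
    squid,
    feeding,
    questionnaires,
    history,
    out_dir: str,
):
    ia_table, s_table, provenance = assoc.build_analysis_tables(
        samples,
        alpha,
        rhythmicity_fits=fits,
        volatility_records=volatility_records,
        circadian=circadian,
        squid=squid,
        feeding=feeding,
        questionnaires=questionnaires,
        history=history,
        melatonin_outlier_sd=cfg.association.melatonin_outlier_sd,
    )
    _write_df(ia_table, os.path.join(out_dir, "table_infant_age.tsv"))
    _write_df(s_table, os.path.join(out_dir, "table_sample.tsv"))
    targets = sorted({f.target for f in fits})
    registry = assoc.default_registry(targets)
    model_fits, summary, failures = assoc.run_model_suite(
        registry, ia_table, s_table, reml=cfg.association.reml
    )
    _write_df(summary, os.path.join(out_dir, "model_fits.tsv"))
    prov_rows = [
        {"stage": p.stage, "detail": p.detail, "count": p.count} for p in provenance
    ] + [{"stage": "association", "detail": f, "count": 1} for f in failures]
    write_long_table(
        prov_rows,
        os.path.join(out_dir, "provenance.tsv"),
        columns=["stage", "detail", "count"],
    )
    logger.info(
        "associate: %d/%d models fit (%d failures)",
        len(model_fits),
        len(registry),
        len(failures),
    )
    return model_fits, summary


def run_pipeline(
    cfg: Config, out_dir: str, bundle_dir: str | None = None
) -> dict:
    """Run every stage in dependency order; returns the in-memory results.

    If *bundle_dir* is None a synthetic cohort is generated from
    ``cfg.synthetic`` under ``out_dir/bundle``.
    """
    os.makedirs(out_dir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(out_dir, "run.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        with open(os.path.join(out_dir, "config_resolved.yaml"), "w") as fh:
            fh.write(dump_config(cfg))
        stage = "input"
        try:
            if bundle_dir is None:
                stage = "simulate"
                bundle = generate_cohort(
                    cfg.synthetic, cfg.seed, os.path.join(out_dir, "bundle")
                )
            else:
                bundle = load_cohort_bundle(
                    bundle_dir, epoch_minutes=cfg.actigraphy.epoch_minutes
                )
            stage = "filter"
            table, samples = stage_filter(cfg, bundle, out_dir)
            stage = "diversity"
            alpha, dms, genus_rel, top = stage_diversity(
                cfg, table, bundle.tree, bundle.taxonomy, out_dir
            )
            stage = "rhythmicity"
            fits = stage_rhythmicity(cfg, alpha, genus_rel, top, samples, out_dir)
            stage = "volatility"
            vrecords = stage_volatility(cfg, dms, samples, out_dir)
            stage = "actigraphy"
            circadian = stage_actigraphy(cfg, bundle.actimetry, out_dir)
            stage = "squid"
            squid = stage_squid(cfg, bundle.questionnaires, out_dir)
            stage = "history"
            history, feeding = stage_history(cfg, samples, bundle.diaries, out_dir)
            stage = "associate"
            model_fits, summary = stage_associate(
                cfg,
                samples,
                alpha,
                fits,
                vrecords,
                circadian,
                squid,
                feeding,
                bundle.questionnaires,
                history,
                out_dir,
            )
        except GutRhythmError as exc:
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
        return {
            "bundle": bundle,
            "table": table,
            "samples": samples,
            "alpha": alpha,
            "distance_matrices": dms,
            "rhythmicity": fits,
            "volatility": vrecords,
            "circadian": circadian,
            "squid": squid,
            "history": history,
            "feeding": feeding,
            "model_fits": model_fits,
            "summary": summary,
        }
    finally:
        logger.removeHandler(handler)
        handler.close()
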