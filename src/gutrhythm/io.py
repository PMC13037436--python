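"""Readers and writers for every input/output format, and the cohort bundle.

On-disk layout of a cohort bundle directory::

    feature_table.tsv   features × samples integer counts (or .biom, HDF5 v2.1)
    taxonomy.tsv        Feature ID <tab> Taxon (semicolon ranks, d__/p__/... ok)
    tree.nwk            rooted Newick, tips = feature ids
    samples.tsv         per-sample metadata
    questionnaires.tsv  per infant-age BISQ/BCQ/ASQ scores
    actimetry.tsv       long table: infant_id, age_group, timestamp, activity, wear
    diary_states.tsv    long table: infant_id, age_group, interval_start, state
    feedings.tsv        long table: infant_id, age_group, feed_time
    ground_truth.json   (optional) simulator ground truth

Missing values are written as empty fields; ``NA`` is also accepted on read.
Datetimes are local wall-clock ISO-8601 without timezone.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, fields as dc_fields, is_dataclass
from datetime import datetime
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

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
from gutrhythm.errors import IntegrityError, ParseError

_NA = ("", "NA")
_DT_FMT = "%Y-%m-%dT%H:%M:%S"

_QIIME_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__")


def format_datetime(dt: datetime) -> str:
    return dt.strftime(_DT_FMT)


def parse_datetime(text: str, where: str = "") -> datetime:
    for fmt in (_DT_FMT, "%Y-%m-%d %H:%M:%S", "%Y-%m-%dT%H:%M"):
        try:
            return datetime.strptime(text, fmt)
        except ValueError:
            continue
    raise ParseError(f"unparseable datetime {text!r}{' in ' + where if where else ''}")


# ---------------------------------------------------------------------------
# feature table


def read_feature_table(path: str) -> FeatureTable:
    if path.endswith(".biom"):
        return _read_biom_hdf5(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot parse feature table {path}: {exc}") from exc
    first = str(df.index.name or "").strip().lower()
    if first in ("feature_id", "feature id", "#otu id", "otu id"):
        # features × samples
        return FeatureTable(
            sample_ids=list(df.columns),
            feature_ids=[str(i) for i in df.index],
            counts=df.to_numpy().T,
        )
    if first in ("sample_id", "sample id"):
        return FeatureTable(
            sample_ids=[str(i) for i in df.index],
            feature_ids=list(df.columns),
            counts=df.to_numpy(),
        )
    raise ParseError(
        f"feature table {path}: header corner must be 'feature_id' or "
        f"'sample_id', got {df.index.name!r}"
    )


def write_feature_table(table: FeatureTable, path: str) -> None:
    df = pd.DataFrame(
        table.counts.T, index=table.feature_ids, columns=table.sample_ids
    )
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


def _read_biom_hdf5(path: str) -> FeatureTable:
    """Minimal BIOM v2.1 (HDF5, CSR by observation) reader."""
    import h5py

    with h5py.File(path, "r") as fh:
        try:
            obs_ids = [x.decode() for x in fh["observation/ids"][:]]
            sample_ids = [x.decode() for x in fh["sample/ids"][:]]
            data = fh["observation/matrix/data"][:]
            indices = fh["observation/matrix/indices"][:]
            indptr = fh["observation/matrix/indptr"][:]
        except KeyError as exc:
            raise ParseError(f"{path} is not a BIOM v2.1 file: missing {exc}") from exc
    import scipy.sparse as sp

    mat = sp.csr_matrix(
        (data, indices, indptr), shape=(len(obs_ids), len(sample_ids))
    )
    return FeatureTable(sample_ids, obs_ids, np.asarray(mat.todense()).T)


# ---------------------------------------------------------------------------
# taxonomy


def parse_taxon_string(taxon: str) -> list[str]:
    ranks = []
    for part in taxon.split(";"):
        part = part.strip()
        for pref in _QIIME_PREFIXES:
            if part.startswith(pref):
                part = part[len(pref):]
                break
        ranks.append(part)
    return ranks


def read_taxonomy(path: str) -> TaxonomyMap:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = {c.strip().lower(): c for c in df.columns}
    fid_col = cols.get("feature id") or cols.get("feature_id")
    tax_col = cols.get("taxon") or cols.get("taxonomy")
    if fid_col is None or tax_col is None:
        raise ParseError(
            f"taxonomy {path}: need 'Feature ID' and 'Taxon' columns, "
            f"got {list(df.columns)}"
        )
    return TaxonomyMap(
        {row[fid_col]: parse_taxon_string(row[tax_col]) for _, row in df.iterrows()}
    )


def write_taxonomy(taxonomy: TaxonomyMap, path: str) -> None:
    prefixes = _QIIME_PREFIXES
    with open(path, "w") as fh:
        fh.write("Feature ID\tTaxon\n")
        for fid, ranks in taxonomy.items():
            labelled = [p + r for p, r in zip(prefixes, ranks)]
            fh.write(f"{fid}\t{'; '.join(labelled)}\n")


# ---------------------------------------------------------------------------
# generic long tables


def _cell(value: Any) -> str:
    if value is None:
        return ""
    if isinstance(value, (bool, np.bool_)):
        return str(int(value))
    if isinstance(value, np.floating):
        value = float(value)
    if isinstance(value, np.integer):
        value = int(value)
    if isinstance(value, float) and math.isnan(value):
        return ""
    if isinstance(value, datetime):
        return format_datetime(value)
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _record_dict(record: Any) -> dict[str, Any]:
    if is_dataclass(record):
        out = {}
        for f in dc_fields(record):
            v = getattr(record, f.name)
            if isinstance(v, InfantAgeKey):
                out["infant_id"] = v.infant_id
                out["age_group"] = v.age_group
            else:
                out[f.name] = v
        return out
    if isinstance(record, Mapping):
        return dict(record)
    raise TypeError(f"cannot serialize record of type {type(record).__name__}")


def write_long_table(records: Sequence[Any], path: str, columns: Sequence[str] | None = None) -> None:
    """Write records (dataclasses or mappings) to a TSV with a stable header.

    Missing values become empty fields; an empty record set yields a
    header-only file (requires explicit *columns* in that case).
    """
    rows = [_record_dict(r) for r in records]
    if columns is None:
        if not rows:
            raise ValueError("empty record set requires explicit columns")
        columns = list(rows[0])
        for row in rows[1:]:
            if list(row) != columns:
                raise ValueError("records do not share one schema")
    try:
        with open(path, "w") as fh:
            fh.write("\t".join(columns) + "\n")
            for row in rows:
                fh.write("\t".join(_cell(row.get(c)) for c in columns) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


def read_long_table(path: str) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=None
    )


def _opt_float(text: str) -> float | None:
    return None if text in _NA else float(text)


# ---------------------------------------------------------------------------
# metadata / questionnaires


def read_samples(path: str) -> list[SampleRecord]:
    df = read_long_table(path)
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                SampleRecord(
                    sample_id=row["sample_id"],
                    infant_id=row["infant_id"],
                    age_group=int(row["age_group"]),
                    age_days=int(row["age_days"]),
                    collection_datetime=parse_datetime(
                        row["collection_datetime"], f"{path}:{i + 2}"
                    ),
                    sex=row["sex"],
                    melatonin_pg_per_g=_opt_float(row["melatonin_pg_per_g"]),
                )
            )
        except (KeyError, ValueError) as exc:
            raise ParseError(f"{path}:{i + 2}: {exc}") from exc
    return records


def write_samples(records: Sequence[SampleRecord], path: str) -> None:
    write_long_table(
        records,
        path,
        columns=[
            "sample_id",
            "infant_id",
            "age_group",
            "age_days",
            "collection_datetime",
            "sex",
            "melatonin_pg_per_g",
        ],
    )


def read_questionnaires(path: str) -> list[QuestionnaireRecord]:
    df = read_long_table(path)
    records = []
    seen: set[InfantAgeKey] = set()
    for i, row in df.iterrows():
        rec = QuestionnaireRecord(
            infant_id=row["infant_id"],
            age_group=int(row["age_group"]),
            bisq_night_sleep_h=_opt_float(row["bisq_night_sleep_h"]),
            bisq_latency_h=_opt_float(row["bisq_latency_h"]),
            bisq_bedtime_clock_h=_opt_float(row["bisq_bedtime_clock_h"]),
            bisq_n_awakenings=_opt_float(row["bisq_n_awakenings"]),
            bcq_attunement=_opt_float(row["bcq_attunement"]),
            asq_composite=_opt_float(row["asq_composite"]),
        )
        if rec.key in seen:
            raise IntegrityError(f"{path}: duplicate questionnaire record {rec.key}")
        seen.add(rec.key)
        records.append(rec)
    return records


def write_questionnaires(records: Sequence[QuestionnaireRecord], path: str) -> None:
    write_long_table(
        records,
        path,
        columns=[
            "infant_id",
            "age_group",
            "bisq_night_sleep_h",
            "bisq_latency_h",
            "bisq_bedtime_clock_h",
            "bisq_n_awakenings",
            "bcq_attunement",
            "asq_composite",
        ],
    )


# ---------------------------------------------------------------------------
# actimetry / diaries


def read_actimetry(path: str, epoch_minutes: int = 1) -> dict[InfantAgeKey, ActivitySeries]:
    df = read_long_table(path)
    out: dict[InfantAgeKey, ActivitySeries] = {}
    for (iid, age), grp in df.groupby(["infant_id", "age_group"], sort=True):
        key = InfantAgeKey(str(iid), int(age))
        out[key] = ActivitySeries(
            key=key,
            epoch_start=[parse_datetime(t, path) for t in grp["timestamp"]],
            activity=grp["activity"].astype(float).to_numpy(),
            wear=grp["wear"].astype(int).to_numpy().astype(bool),
            epoch_minutes=epoch_minutes,
        )
    return out


def write_actimetry(series: Mapping[InfantAgeKey, ActivitySeries], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("infant_id\tage_group\ttimestamp\tactivity\twear\n")
        for key in sorted(series):
            s = series[key]
            for t, a, w in zip(s.epoch_start, s.activity, s.wear):
                fh.write(
                    f"{key.infant_id}\t{key.age_group}\t{format_datetime(t)}"
                    f"\t{float(a)!r}\t{int(w)}\n"
                )


def read_diaries(states_path: str, feedings_path: str) -> dict[InfantAgeKey, DiaryTimeline]:
    states = read_long_table(states_path)
    feeds = read_long_table(feedings_path)
    out: dict[InfantAgeKey, DiaryTimeline] = {}
    for (iid, age), grp in states.groupby(["infant_id", "age_group"], sort=True):
        key = InfantAgeKey(str(iid), int(age))
        out[key] = DiaryTimeline(
            key=key,
            interval_start=[parse_datetime(t, states_path) for t in grp["interval_start"]],
            is_sleep=(grp["state"] == "sleep").to_numpy(),
        )
    for (iid, age), grp in feeds.groupby(["infant_id", "age_group"], sort=True):
        key = InfantAgeKey(str(iid), int(age))
        times = [parse_datetime(t, feedings_path) for t in grp["feed_time"]]
        if key in out:
            out[key].feed_times = sorted(times)
        else:
            out[key] = DiaryTimeline(key=key, interval_start=[], is_sleep=np.zeros(0), feed_times=times)
    return out


def write_diaries(
    diaries: Mapping[InfantAgeKey, DiaryTimeline],
    states_path: str,
    feedings_path: str,
) -> None:
    with open(states_path, "w") as fh:
        fh.write("infant_id\tage_group\tinterval_start\tstate\n")
        for key in sorted(diaries):
            d = diaries[key]
            for t, s in zip(d.interval_start, d.is_sleep):
                fh.write(
                    f"{key.infant_id}\t{key.age_group}\t{format_datetime(t)}"
                    f"\t{'sleep' if s else 'wake'}\n"
                )
    with open(feedings_path, "w") as fh:
        fh.write("infant_id\tage_group\tfeed_time\n")
        for key in sorted(diaries):
            for t in diaries[key].feed_times:
                fh.write(f"{key.infant_id}\t{key.age_group}\t{format_datetime(t)}\n")


# ---------------------------------------------------------------------------
# cohort bundle


@dataclass
class CohortBundle:
    """All pipeline inputs for one cohort, plus optional simulator ground truth."""

    table: FeatureTable
    taxonomy: TaxonomyMap
    tree: RootedTree
    samples: list[SampleRecord]
    questionnaires: list[QuestionnaireRecord] = field(default_factory=list)
    actimetry: dict[InfantAgeKey, ActivitySeries] = field(default_factory=dict)
    diaries: dict[InfantAgeKey, DiaryTimeline] = field(default_factory=dict)
    ground_truth: dict | None = None

    def sample_by_id(self, sample_id: str) -> SampleRecord:
        for rec in self.samples:
            if rec.sample_id == sample_id:
                return rec
        raise KeyError(sample_id)

    def infants(self) -> list[str]:
        return sorted({r.infant_id for r in self.samples})


BUNDLE_FILES = {
    "table": "feature_table.tsv",
    "taxonomy": "taxonomy.tsv",
    "tree": "tree.nwk",
    "samples": "samples.tsv",
    "questionnaires": "questionnaires.tsv",
    "actimetry": "actimetry.tsv",
    "diary_states": "diary_states.tsv",
    "feedings": "feedings.tsv",
    "ground_truth": "ground_truth.json",
}


def write_cohort_bundle(bundle: CohortBundle, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    p = lambda name: os.path.join(out_dir, BUNDLE_FILES[name])  # noqa: E731
    write_feature_table(bundle.table, p("table"))
    write_taxonomy(bundle.taxonomy, p("taxonomy"))
    with open(p("tree"), "w") as fh:
        fh.write(bundle.tree.to_newick())
    write_samples(bundle.samples, p("samples"))
    write_questionnaires(bundle.questionnaires, p("questionnaires"))
    write_actimetry(bundle.actimetry, p("actimetry"))
    write_diaries(bundle.diaries, p("diary_states"), p("feedings"))
    if bundle.ground_truth is not None:
        with open(p("ground_truth"), "w") as fh:
            json.dump(bundle.ground_truth, fh, indent=1, sort_keys=True)


def load_cohort_bundle(bundle_dir: str, epoch_minutes: int = 1) -> CohortBundle:
    """Load a bundle directory and enforce cross-referential integrity."""
    p = lambda name: os.path.join(bundle_dir, BUNDLE_FILES[name])  # noqa: E731
    for name in ("table", "taxonomy", "tree", "samples"):
        if not os.path.exists(p(name)):
            raise ParseError(f"missing bundle file: {p(name)}")
    table = read_feature_table(p("table"))
    taxonomy = read_taxonomy(p("taxonomy"))
    with open(p("tree")) as fh:
        tree = RootedTree.from_newick(fh.read())
    samples = read_samples(p("samples"))
    questionnaires = (
        read_questionnaires(p("questionnaires"))
        if os.path.exists(p("questionnaires"))
        else []
    )
    actimetry = (
        read_actimetry(p("actimetry"), epoch_minutes)
        if os.path.exists(p("actimetry"))
        else {}
    )
    diaries = (
        read_diaries(p("diary_states"), p("feedings"))
        if os.path.exists(p("diary_states")) and os.path.exists(p("feedings"))
        else {}
    )
    ground_truth = None
    if os.path.exists(p("ground_truth")):
        with open(p("ground_truth")) as fh:
            ground_truth = json.load(fh)

    table_samples = set(table.sample_ids)
    orphan = sorted(r.sample_id for r in samples if r.sample_id not in table_samples)
    if orphan:
        raise IntegrityError(
            f"metadata sample ids missing from feature table: {orphan[:10]}"
        )
    tree.tip_columns(table.feature_ids)  # raises if any feature lacks a tip

    return CohortBundle(
        table=table,
        taxonomy=taxonomy,
        tree=tree,
        samples=samples,
        questionnaires=questionnaires,
        actimetry=actimetry,
        diaries=diaries,
        ground_truth=ground_truth,
    )
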