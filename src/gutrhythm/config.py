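"""Configuration schema with per-stage sections and YAML loading.

Every threshold, seed, and tolerance used by the pipeline lives here with
its documented default, so a single config file fully determines a run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

from gutrhythm.errors import ConfigError


@dataclass
class FilterConfig:
    min_feature_total: int = 10
    min_depth: int = 3035
    # phylum → feature frequency → sample depth; overridable order
    order: tuple[str, ...] = ("phylum", "feature_total", "sample_depth")


@dataclass
class DiversityConfig:
    depth: int = 3035
    n_boot: int = 100
    weighted_unifrac_normalized: bool = False
    # genus relative abundances from raw filtered counts (not rarefied)
    genus_abundance_source: str = "raw_filtered"
    top_k_genera: int = 5


@dataclass
class RhythmicityConfig:
    min_samples: int = 4
    period_h: float = 24.0


@dataclass
class VolatilityConfig:
    n_axes: int = 3
    embedding_scope: str = "cohort"  # or "group"


@dataclass
class ActigraphyConfig:
    epoch_minutes: int = 1
    min_days: int = 3
    min_wear_fraction: float = 0.5


@dataclass
class SquidConfig:
    max_missing: int = 2
    day_sd_aggregation: str = "mean"  # feeding rhythmicity day-level aggregation
    # optional plausibility screens, off by default
    max_night_sleep_h: float | None = None
    max_latency_h: float | None = None


@dataclass
class AssociationConfig:
    melatonin_outlier_sd: float = 8.0
    reml: bool = True


@dataclass
class AgeGroupSpec:
    age_group: int
    age_days_mean: float
    age_days_sd: float = 5.0


@dataclass
class GenusSpec:
    name: str
    family: str
    phylum: str
    baseline_log: float
    amplitude: float = 0.0  # diurnal amplitude on log abundance
    acrophase_h: float = 0.0  # clock hour of peak
    n_asvs: int = 4


def _default_genera() -> list[GenusSpec]:
    # five planted dominant genera (two oscillating) + minor background genera
    return [
        GenusSpec("Bifidobacterium", "Bifidobacteriaceae", "Actinobacteriota", 4.0, 0.0, 0.0, 6),
        GenusSpec("Escherichia-Shigella", "Enterobacteriaceae", "Proteobacteria", 3.6, 0.6, 14.0, 5),
        GenusSpec("Veillonella", "Veillonellaceae", "Firmicutes", 3.3, 0.0, 0.0, 5),
        GenusSpec("Bacteroides", "Bacteroidaceae", "Bacteroidota", 3.1, 0.8, 8.0, 5),
        GenusSpec("Clostridium sensu stricto 1", "Clostridiaceae", "Firmicutes", 2.9, 0.0, 0.0, 5),
        GenusSpec("Streptococcus", "Streptococcaceae", "Firmicutes", 1.6, 0.0, 0.0, 4),
        GenusSpec("Enterococcus", "Enterococcaceae", "Firmicutes", 1.3, 0.0, 0.0, 4),
        GenusSpec("Klebsiella", "Enterobacteriaceae", "Proteobacteria", 1.2, 0.0, 0.0, 4),
        GenusSpec("Lactobacillus", "Lactobacillaceae", "Firmicutes", 1.0, 0.0, 0.0, 4),
        GenusSpec("Sutterella", "Sutterellaceae", "Proteobacteria", 0.8, 0.0, 0.0, 3),
        GenusSpec("Akkermansia", "Akkermansiaceae", "Verrucomicrobiota", 0.6, 0.0, 0.0, 3),
        GenusSpec("Collinsella", "Coriobacteriaceae", "Actinobacteriota", 0.5, 0.0, 0.0, 3),
    ]


@dataclass
class SyntheticCohortConfig:
    n_infants: int = 20
    age_groups: list[AgeGroupSpec] = field(
        default_factory=lambda: [
            AgeGroupSpec(2, 76.0),
            AgeGroupSpec(4, 128.0),
            AgeGroupSpec(6, 190.0),
        ]
    )
    # samples per infant-age: 1 + Binomial(10, p) with p tuned for median 4
    samples_median: int = 4
    samples_max: int = 11
    window_h: float = 48.0
    genera: list[GenusSpec] = field(default_factory=_default_genera)
    infant_effect_sd: float = 0.4
    log_noise_sd: float = 0.3
    richness_age_slope: float = 0.1  # detectable features per day of age
    baseline_present_fraction: float = 0.45
    phylum_unassigned_fraction: float = 0.05
    n_rare_features: int = 8  # planted features with total count < 10
    library_size_log_mean: float = 9.2
    library_size_log_sd: float = 0.25
    library_size_min: int = 4000
    # actigraphy
    activity_mesor: float = 50.0
    relative_amplitude: float = 0.8
    fragmentation_per_h: float = 0.05
    peak_hour: float = 14.0
    activity_noise_sd: float = 2.0
    days_mean: float = 8.0
    days_min: int = 3
    days_max: int = 11
    nonwear_fraction: float = 0.0
    # diary / questionnaires
    feed_interval_mean_h: float = 3.0
    feed_interval_jitter_h: float = 0.5
    diary_jitter_min: float = 0.0
    bisq_night_sleep_base_h: float = 8.0
    bisq_night_sleep_slope_per_day: float = 0.01
    bisq_latency_base_h: float = 0.6
    bisq_latency_slope_per_day: float = -0.001
    bisq_bedtime_base_h: float = 20.5
    bisq_awakenings_base: float = 3.0
    bisq_awakenings_slope_per_day: float = -0.01
    bisq_noise_sd: float = 0.3
    bisq_missing_fraction: float = 0.0
    bcq_mean: float = 0.5
    bcq_sd: float = 0.15
    asq_mean: float = 250.0
    asq_sd: float = 30.0
    melatonin_intercept: float = 20.0
    melatonin_age_slope: float = 0.638
    melatonin_noise_sigma: float = 0.4  # sigma of the additive log-normal noise
    sex_female_ratio: float = 0.5

    def validate(self) -> None:
        if self.n_infants < 1:
            raise ConfigError("n_infants must be ≥ 1")
        if self.library_size_min <= 0:
            raise ConfigError("library_size_min must be positive")
        if not 1 <= self.samples_median <= self.samples_max <= 11:
            raise ConfigError("samples per infant-age support must lie in [1, 11]")
        if self.activity_mesor <= 0:
            raise ConfigError("activity_mesor must be positive")
        if 60 % 1 != 0:
            raise ConfigError("epoch length must divide 60 minutes")


@dataclass
class Config:
    seed: int = 0
    filter: FilterConfig = field(default_factory=FilterConfig)
    diversity: DiversityConfig = field(default_factory=DiversityConfig)
    rhythmicity: RhythmicityConfig = field(default_factory=RhythmicityConfig)
    volatility: VolatilityConfig = field(default_factory=VolatilityConfig)
    actigraphy: ActigraphyConfig = field(default_factory=ActigraphyConfig)
    squid: SquidConfig = field(default_factory=SquidConfig)
    association: AssociationConfig = field(default_factory=AssociationConfig)
    synthetic: SyntheticCohortConfig = field(default_factory=SyntheticCohortConfig)


def _update_dataclass(obj: Any, data: dict) -> Any:
    fields = {f.name: f for f in dataclasses.fields(obj)}
    for key, value in data.items():
        if key not in fields:
            raise ConfigError(f"unknown config key {key!r} in {type(obj).__name__}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current) and isinstance(value, dict):
            _update_dataclass(current, value)
        elif key == "age_groups":
            setattr(obj, key, [AgeGroupSpec(**v) for v in value])
        elif key == "genera":
            setattr(obj, key, [GenusSpec(**v) for v in value])
        else:
            setattr(obj, key, value)
    return obj


def load_config(path: str | None = None, overrides: dict | None = None) -> Config:
    """Build a :class:`Config` from an optional YAML file plus overrides."""
    cfg = Config()
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        _update_dataclass(cfg, data)
    if overrides:
        _update_dataclass(cfg, overrides)
    return cfg


def dump_config(cfg: Config) -> str:
    """YAML snapshot of a fully-resolved config."""
    return yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=False)
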