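# gutrhythm

Analysis pipeline linking temporal structure of the infant gut microbiota —
diurnal cosinor rhythmicity, PCoA-centroid temporal volatility, and
bootstrapped alpha/beta diversity — to sleep maturation metrics (the
Circadian Function Index from actimetry and a questionnaire-based
sleep-quality composite) through a suite of random-intercept linear mixed
models. A synthetic-cohort generator produces every input format with known
ground truth, so the whole pipeline is testable without external data.

## Modules

| Module | What it does |
| --- | --- |
| `gutrhythm.datamodel` | Shared data contracts (feature table, taxonomy, rooted tree, sample/questionnaire records) with validated invariants |
| `gutrhythm.io` | TSV/BIOM/Newick readers and writers, cohort bundle round-trip |
| `gutrhythm.simulate` | Synthetic cohort: diurnally modulated multinomial counts, random phylogeny, actimetry, 15-min diaries, questionnaires, melatonin, ground-truth JSON |
| `gutrhythm.diversity` | Phylum/frequency/depth filters, rarefaction, bootstrapped alpha (observed features, Shannon, Pielou, Faith PD) and beta (Bray–Curtis, Jaccard, unweighted/weighted UniFrac) metrics, genus collapse, PCoA |
| `gutrhythm.rhythmicity` | Fixed-24-h cosinor fits (amplitude, acrophase, mesor, R²) per infant-age series |
| `gutrhythm.volatility` | Median distance of an infant-age's samples to their centroid in a 3-axis PCoA embedding |
| `gutrhythm.actigraphy` | Interdaily stability, intradaily variability, relative amplitude, CFI = (IS + (2−IV)/2 + RA)/3 |
| `gutrhythm.sleep_behavior` | BabySQUID composite (min-max scaling, reverse coding, median imputation), diary-derived sleep/feeding history, feeding rhythmicity |
| `gutrhythm.association` | Analysis-table assembly (median aggregation, covariate imputation, melatonin outlier rule) and the REML mixed-model registry |
| `gutrhythm.pipeline` | Stage orchestration; byte-identical reruns under a fixed seed |

## CLI

```bash
# generate a synthetic cohort bundle
gutrhythm simulate --seed 1 --out-dir run/bundle

# run everything (simulates a cohort if --bundle-dir is omitted)
gutrhythm all --seed 1 --out-dir run

# individual stages
gutrhythm diversity  --bundle-dir run/bundle --out-dir run --depth 3035 --n-boot 100
gutrhythm rhythmicity --bundle-dir run/bundle --out-dir run --min-samples 4 --top-genera 5
gutrhythm volatility --bundle-dir run/bundle --out-dir run --n-axes 3
gutrhythm actigraphy --bundle-dir run/bundle --out-dir run --min-days 3
gutrhythm squid      --bundle-dir run/bundle --out-dir run
gutrhythm history    --bundle-dir run/bundle --out-dir run
```

Global flags: `--config <yaml>`, `--seed`, `--out-dir`, `--log-level`.
Every threshold (filter depths, bootstrap count, cosinor minimum samples,
CFI day rule, model registry options …) is a config key with its documented
default; `config_resolved.yaml` is written into every run directory.

Outputs are plain TSV: per-sample alpha diversity, per-metric distance
matrices, cosinor fits, volatility records, circadian metrics, BabySQUID
components, history covariates, `model_fits.tsv` (coefficients, SEs, Wald
p-values per model) and `provenance.tsv` (every exclusion/imputation).

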