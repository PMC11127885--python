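# weedclass

Classify archaeobotanical weed assemblages against two-group models of
modern farming regimes using functional weed ecology.

The package takes a raw taxa-by-samples seed-count matrix, converts it to
presence/absence, averages species-level functional traits (SLA, ARNODE,
LOGCANH, LOGCAND, VEGPROP, FLOWPER) per sample, fits a two-group linear
discriminant on a modern reference survey dataset, classifies each sample
(group 1 vs group 2 with posterior probabilities), and plots discriminant
scores as beeswarms against the model fields and centroids.

## Modules

| module               | role |
|----------------------|------|
| `weedclass.traitdb`  | species trait database, four-three species codes, CSV import/export |
| `weedclass.organise` | presence/absence, composite-taxon averaging, FLOWPER merge, VEGPROP overrides, min-seed cleaning, per-sample trait profiles |
| `weedclass.lda`      | two-group discriminant fit/classify, built from first principles (pooled within-group covariance, unit within-group LD1 variance, group 1 positive) |
| `weedclass.viz`      | `basic` / `geog` / `phase` beeswarm layouts (deterministic swarm; byte-stable SVG) |
| `weedclass.synth`    | synthetic trait databases, reference datasets and count matrices with known ground truth |
| `weedclass.cli`      | `weedclass` command-line entry point and the full pipeline with a provenance manifest |

The packaged reference datasets (`weedclass/data/model*_reference.csv`) are
clearly-labelled **synthetic stand-ins** with the published schema
(`group,location,<predictors>`); a real released reference CSV loads through
the same `lda.load_model_data(path, model_id=...)` call.
`weedclass/data/stafford_composites.csv` is the worked-example
composite-taxon mapping (12 composite taxa) in the composite-spec CSV format.

## CLI

```sh
# derive a four-three species code
weedclass codes --genus Agrostemma --epithet githago        # -> agrogit

# generate a complete synthetic fixture set
weedclass simulate --preset model1 --seed 42 --out-dir fixtures/

# organise -> classify -> plot, step by step
weedclass organise --counts fixtures/counts.csv --db fixtures/db.csv \
    --model 1 --flowper fixtures/flowper.csv --out profiles.csv
weedclass classify --profiles profiles.csv --model 1 \
    --model-data fixtures/model_data.csv --out results.csv
weedclass plot --results results.csv --profiles profiles.csv --model 1 \
    --model-data fixtures/model_data.csv --layout basic --out fig.svg

# or the whole pipeline from a YAML config (writes manifest.json too)
weedclass run --config run.yaml
```

A minimal `run.yaml`:

```yaml
counts: fixtures/counts.csv
db: fixtures/db.csv
flowper: fixtures/flowper.csv
model: 1
model_data: fixtures/model_data.csv
min_seeds: 10
out_dir: out
```

## Conventions that matter

* Trait means divide by the number of contributing species with a
  *non-missing* value for that trait; missing VEGPROP shrinks the
  denominator instead of counting as zero.
* Samples with fewer than 10 weed seeds are dropped by `clean_samples`
  (threshold configurable); samples with fewer than 3 species are flagged,
  never dropped.
* LD1 is scaled to unit pooled within-group variance, zeroed at the
  prior-weighted grand mean, and signed so group 1 is positive.
* Priors default to group proportions; `--equal-priors` overrides.
* A posterior of exactly 0.5 classifies as group 2.

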