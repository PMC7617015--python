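# oxrec

Fixed-horizon violent-reoffending risk scoring with the full external
validation toolchain: scoring (proportional-hazards risk transform with
absent-predictor adjustment), synthetic cohort simulation, multiple
imputation by chained equations, a discrimination/calibration metric battery,
and the incremental recalibration strategy (simple validation → baseline-risk
update with multiplicative slope → coefficient comparison).

The real release cohorts behind the tool are not publicly available, so the
package ships a seeded synthetic-cohort generator that reproduces the
published predictor margins (`england` and `sweden` presets), per-predictor
missingness rates, the three wholly absent predictors, and realistic 1-/2-year
event rates. Every pipeline stage is exercisable end to end without any real
criminal-justice data.

## The model

Risk at horizon *t* ∈ {12, 24} months is

```
risk_t = 1 − S_t ^ exp( slope_t × (adjustment + Σ beta × RF) )
```

where `S_t` is the baseline survival, `slope_t` a multiplicative
recalibration factor, and `adjustment` folds wholly absent predictors in as
`Σ beta × derivation-prevalence`. Two configuration presets ship:

- `sweden_original` — slope 1, no absent predictors, `S_12 = 0.7992`,
  `S_24 = 0.6775`;
- `england_updated` — slopes `0.6745` / `0.5372`, `S_12 = 0.4643`,
  `S_24 = 0.3509`, and the seven published beta×prevalence products for
  highest education, disposable income and severe mental disorder
  (adjustment ≈ 0.3255).

The development-study betas are not reproduced in the validation source; the
preset files carry clearly flagged placeholder weights (see
`metadata.placeholder_betas` in the YAML) that must be replaced before any
real-world use. All published values (slopes, baselines, the seven products)
are exact.

## CLI

```bash
# draw a synthetic cohort (margins + missingness presets, CSV + metadata)
oxrec simulate --preset england --model england_updated --n 2000 --seed 1 --out cohort.csv

# multiply-impute partially missing predictors (m completed CSVs + manifest)
oxrec impute --in cohort.csv --m 20 --seed 1 --out-dir imputed/

# score a complete cohort: appends lp, risk_12m/24m, category_12m/24m
oxrec score --model england_updated --in imputed/imputed_00.csv --out scored.csv

# full incremental validation: (MICE if needed) → simple validation →
# conditional update → report bundle (report.md, metrics.csv, figures, audit)
oxrec validate --model sweden_original --in cohort.csv --out-dir validation/ --seed 1

# force the step-2 update and write the updated configuration
oxrec recalibrate --model sweden_original --in complete.csv --out updated.yaml

# re-render a Markdown summary from a saved metrics CSV
oxrec report --metrics validation/metrics.csv --out summary.md
```

Recalibration modes: `--mode cox` (one proportional-hazards slope shared
across horizons, fitted on time-to-event data) or `--mode per_horizon`
(independent complementary-log-log binary fits, giving horizon-specific
slopes — the structure of the published updated model). In both modes the
baseline survival is re-solved so that mean predicted risk equals the
observed event rate on the fitting data.

## Python API

```python
import oxrec

model = oxrec.load_preset("england_updated")
spec = oxrec.preset_spec("england", n=5000, true_coefs=model.coefs, seed=7)
cohort = oxrec.simulate_cohort(spec)
imputed = oxrec.mice_impute(cohort, m=20, seed=7)
pooled, per_imp = oxrec.run_incremental_pooled(imputed, model)
print(pooled.fitted_slope, pooled.updated_baseline)
```

Key modules: `oxrec.core` (scoring arithmetic), `oxrec.config` (YAML model
configurations), `oxrec.cohort` (simulator), `oxrec.impute` (MICE + Rubin
pooling), `oxrec.metrics` (AUC/threshold/calibration battery),
`oxrec.recalibrate` (incremental strategy), `oxrec.cli`.

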