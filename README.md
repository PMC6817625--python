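# voxpath

Analysis pipeline for speech-and-singing voice studies: deterministic
acoustic transforms (semitone pitch, F0 range, formant spacing, apparent
vocal-tract length), rater-panel aggregation with Cronbach's alpha, generic
comparison statistics, and an observed-variable path-model engine with
permutation-null p-values, jackknife stability certification and two-group
invariance testing. A calibrated synthetic-cohort generator makes every
stage testable end to end without any external data.

## Layout

| module | contents |
| --- | --- |
| `voxpath.acoustics` | Hz→semitone, note labelling, F0 range, ΔF (through-origin slope on the uniform-tube pattern), VTL = c/2ΔF, per-person profiles |
| `voxpath.ratings` | rating matrices, Cronbach's alpha, per-target means, cross-panel agreement with Fisher-z CIs |
| `voxpath.stats` | Pearson (t-based p, Fisher CI), Kendall tau-b, paired t, Type-III two-way ANOVA with partial eta-squared and marginal means |
| `voxpath.path_model` | path-model spec (38 regressions + 6 exogenous covariances by default), ML chi-square via the RAM implied covariance, permutation p-values, jackknife stability, configural vs path-invariant chi-square difference (df = 44) |
| `voxpath.synthetic_data` | seeded cohort/rating generators calibrated to the published group summaries (`voxpath/data/default_calibration.yaml`) |
| `voxpath.io` / `voxpath.cli` | CSV schemas with row-level validation, pipeline config, `voxpath` command |

## Command line

```sh
voxpath simulate --seed 11 --out data/          # cohort.csv, recordings.csv, ratings.csv
voxpath acoustics --recordings data/recordings.csv --out profiles.csv
voxpath ratings --ratings data/ratings.csv --out-dir out/
voxpath fit --cohort data/cohort.csv -B 1000 --seed 1 --out pathfit.json
voxpath invariance --cohort data/cohort.csv --group sex --out invariance.json
voxpath report --cohort data/cohort.csv --out stats.csv
voxpath run --config config.yaml [--seed N] [--permutations B] [--mediator f0|vtl]
```

`run` executes the whole pipeline (profiles → rating aggregation → stats →
path fits per sex with permutation p-values and jackknife flags → invariance
tests) and writes a manifest with the seed, config hash and parameter
counts. Exit codes: 0 success, 2 validation error, 3 convergence failure.

A minimal `config.yaml`:

```yaml
recordings: data/recordings.csv
cohort: data/cohort.csv
ratings: data/ratings.csv
out_dir: out
permutations: 1000
seed: 1
```

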