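# dietconn

Diet-adherence scoring, resting-state internetwork connectivity summaries,
and moderation analysis, exercised end-to-end on a synthetic cohort
generator with planted, recoverable effects.

## What it does

- **`dietconn.ffq`** — converts food-frequency intake (servings/month for 11
  food categories) into a 0–55 adherence score: 0–5 frequency categories via
  a monotone cutpoint rule, reverse-scoring of the four detrimental
  categories, beneficial/detrimental subscores, and tertile grouping
  (low / moderate / high, boundary ties fall low).
- **`dietconn.rsfc`** — ROI time-series pipeline: framewise displacement
  (translations + 50 mm-sphere arc length), scrubbing by interpolation,
  zero-phase 0.01–0.08 Hz band-pass, nuisance residualization, Fisher-z
  connectivity matrices with self / <20 mm / non-positive exclusions, and
  internetwork means (1 overall, 10 per-network, 45 pairwise).
- **`dietconn.cognition`** — z-scores 12 in-scanner tasks against reference
  norms and averages them into four ability composites (SPEED, FLUID,
  MEMORY, VOCAB).
- **`dietconn.cohort`** — sequential exclusion cascade
  (diet → connectivity → structural → cognition) with a flow report,
  covariate preparation (ln(WMH+1), indicator coding), and the scrub>30%
  sensitivity filter.
- **`dietconn.models`** — the OLS family: diet main effects on
  connectivity, group × connectivity interaction models (low reference,
  2-df Wald joint test), stratified slopes, per-network and pairwise scans,
  continuous food-subscore interactions, three-way age/gender models, and
  group descriptives (ANOVA / chi-square). Wald 95% CIs (B ± 1.96·SE) with
  a t-interval switch.
- **`dietconn.synthetic`** — generates all of the above inputs under known
  parameters: block-structured ROI covariance with participant-varying
  cross-network correlation, covariates calibrated to published summary
  statistics, ability scores with group-specific connectivity slopes, and
  disjoint sequential missingness (108/22/87/7 from 425 → 201). Fast mode
  draws the connectivity scalar directly; full mode generates frames × ROIs
  series the pipeline can process. Ground truth is stored alongside every
  cohort.
- **`dietconn.simstudy`** — replicate-level recovery studies (planted-slope
  recovery, null calibration of the interaction test).

## CLI

```sh
# one-shot pipeline: simulate -> score -> connectivity -> assemble -> analyze -> report
dietconn run --config config.yaml --seed 1 --out out/ --fast

# stage by stage
dietconn simulate --preset tab2-stratified --seed 1 --n 201 --out sim/ --fast
dietconn score-medi --ffq sim/ffq.csv --out medi.csv
dietconn connectivity --in sim/ --parcellation sim/parcellation.tsv --out rsfc.csv
dietconn assemble --participants sim/participants.csv --medi medi.csv \
    --rsfc sim/rsfc_summaries.csv --ra sim/ra_scores.csv --out analytic.csv
dietconn analyze --analytic analytic.csv --scan overall --out models.csv
dietconn report --analytic analytic.csv --out tables/
```

`run` writes a `manifest.json` recording the config hash, seed, stage
inputs/outputs and every defaulted analysis constant (cutpoints, FD
threshold, filter band and stage order, CI flavor). Re-running with the
same config and seed reproduces the analytic tables byte-for-byte.

Config is YAML; every knob has a documented default (see
`dietconn.cli.DEFAULT_CONFIG` and the `SimulationConfig` dataclass).

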