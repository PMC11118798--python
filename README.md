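# sapm

Structural and physiological modeling (SAPM) of BOLD fMRI time-courses over
a predefined directed network with latent external inputs, plus everything
needed to exercise it end to end without real scan data:

- **`sapm.network`** — directed network models (regions, connections,
  latent inputs), YAML/JSON I/O, validation, adjacency utilities. Ships a
  default brainstem / cervical spinal cord pain-regulation network with
  10 regions, 32 inter-region connections, and 3 latent inputs
  (`src/sapm/networks/fm_brainstem_cord.yaml`).
- **`sapm.synth`** — synthetic data: stimulation paradigms (270-s runs at
  TR 6.75 s, cue at 60 s, a 30-s block of ten 1.5-s heat contacts in the
  Pain condition), canonical double-gamma HRF, latent neural drives,
  network-structured participant/cohort generation with configurable
  ground-truth connection weights, pain-rating covariates,
  phase-randomized surrogates, and NIfTI fixtures.
- **`sapm.roi`** — voxel extraction from 4-D images + integer label maps
  and balanced k-means parcellation of each region into five near-equal
  sub-regions, yielding sub-region mean time-courses.
- **`sapm.model`** — the generative forward model `O = (I - A)^-1 M L` and
  the per-participant fitter: alternating least squares recovering one
  signed weight (DB value) per connection, latent time-courses, and the
  best sub-region combination; null references from surrogate fits;
  derived per-source output shares (D values); input/output signal
  decomposition per region.
- **`sapm.stats`** — group statistics: null-referenced one-sample t-tests
  with Bonferroni correction over the 32 inter-region connections,
  weight-vs-pain-rating regression, group x covariate ANCOVA, and a
  Table-style report.
- **`sapm.cli`** — a `sapm` command orchestrating simulate -> fit -> stats
  from one YAML config with reproducible seeding and a hashed manifest.

## CLI

```bash
# full synthetic pipeline: cohort generation, per-participant fits, stats
sapm run --seed 1 --out runs/demo

# individual stages
sapm simulate --config config.yaml
sapm fit --config config.yaml
sapm stats --config config.yaml
sapm report --out runs/demo
```

A config YAML may set any `PipelineConfig` field, e.g.

```yaml
mode: synthetic        # or "study" with timecourse_csv / covariate_csv
n_per_group: 15
noise_sd: 0.1
ground_truth: table2   # tabulated group/condition weights, or "zero"
subregion_selection: known   # known | greedy | first
alpha_family: 0.05
tails: two_sided       # "upper" reproduces the reported |t| >= 3.563 rule
```

Outputs: `timecourses.csv`, `covariates.csv`, per-participant fit JSONs,
`group_stats.csv`, `regression.csv`, `ancova.csv`, `report.md`,
`manifest.json` (content hashes; bit-for-bit reproducible in synthetic
mode), `run.log`.

## Notes on conventions

- The printed `±` uncertainties on group connectivity values are treated
  as SEMs at n = 15; synthetic between-participant SD defaults to
  `sem * sqrt(15)` (configurable).
- `t_critical(alpha, df)` is the upper-tail quantile
  (`t_critical(0.05/32, 14) = 3.563`). Significance testing defaults to
  two-sided p-values against the corrected alpha, which keeps the
  familywise error at its nominal level; `tails="upper"` applies the
  reported `|t| >= t_critical(alpha)` rule instead.
- Free-form latent inputs make connections *into* latent-bearing regions
  identifiable only up to the latent's overlap with the region's observed
  sources; connections into purely observed regions (including all
  acceptance targets) are recovered consistently.
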