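# oardose

Dosimetric evaluation of autosegmented brain organs-at-risk (OARs), built
as a reusable pipeline:

* **DVH dose statistics** — D1%, D5%, D50% (minimum dose to the most
  exposed x% of the structure volume, discrete cumulative-DVH rule) and
  single-voxel Dmax, in cGy.
* **Geometric agreement** — Dice similarity coefficient, sensitivity and
  symmetric mean distance-to-agreement (face-connectivity surface voxels,
  anisotropy-aware voxel-centre distances).
* **Clinical-significance classification** — per-organ, per-protocol
  thresholds at 50% of the dose headroom to tolerance (average headroom
  for first-order OARs, worst-case headroom for mean-dose-like second-order
  OARs, descriptive-only for the rest), with negative-headroom exclusion
  and strict either-direction flagging.
* **Cohort statistics** — absolute-average percent dose-change tables with
  successful-segmentation counts (N*), paired two-tailed t-tests with
  Bonferroni-corrected alpha, and Pearson correlations between geometric
  metrics and absolute percent dose change.
* **Synthetic cohorts** — a 13-organ head phantom with a logistic-falloff
  VMAT-like dose field (controllable gradient location) and parameterized
  autosegmentation error modes: dilation, erosion, translation, slice
  truncation, gross mislocation and outright failure to segment.

Failed segmentations are first-class: they carry no dose or geometry
metrics (never a silent 0 or DSC = 0), are excluded from means, and feed
the failure tallies.

## CLI

```bash
# generate a synthetic cohort (NIfTI volumes + manifest.json)
oardose simulate --n-cases 10 --seed 1 --out cohort/

# per-case dose metric and geometry tables
oardose evaluate cohort/manifest.json --out reports/

# significance thresholds and flagged cases
oardose classify cohort/manifest.json --out reports/

# cohort table, paired model tests, correlations
oardose stats cohort/manifest.json --out reports/

# everything at once, plus a machine-readable run log
oardose report cohort/manifest.json --out reports/
```

Analysis settings (OAR tolerance table, protocols, percent-change
normalization, alpha, model families) live in a YAML config passed via
`--config`; defaults reproduce the glioma radical-primary VMAT constraint
set (protocol A: 6000 cGy / 30 fractions, protocol B: 5400 cGy / 30
fractions). Doses are cGy everywhere. Exit code 2 signals manifest
validation failure, 3 a computational failure.

## Layout

```
src/oardose/
  core_grid.py     voxel-grid model, compatibility, resampling, NIfTI I/O
  synthetic.py     phantom spec, dose model, perturbations, cohort simulation
  dvh.py           DVH metrics and gold-vs-auto dose deltas
  geometry.py      DSC / sensitivity / mean DTA
  significance.py  headroom thresholds and case flagging
  stats.py         aggregation, paired tests, correlations
  config.py        tolerance table, protocols, run configuration
  manifest.py      cohort manifest read/write and validation
  pipeline.py      end-to-end orchestration and report writers
  cli.py           click CLI
tests/             pytest suite; oracles.py holds independent brute-force
                   references; test_acceptance.py maps 1:1 to the
                   acceptance criteria
```
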