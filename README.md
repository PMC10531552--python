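# suvadc

Voxel-wise combined metabolic (SUV) and functional (ADC) tumor subvolume
analysis for paired PET/MRI volumes, exercised end-to-end on synthetic
phantom cohorts.

The pipeline takes, per patient and timepoint (baseline / post-therapy), a
co-registered SUV volume, an ADC map and a binary tumor mask (NIfTI-1), and:

1. resamples the SUV volume onto the MR analysis grid (0.7 × 0.7 × 5 mm) and
   extracts one (ADC, SUV) record per mask voxel;
2. excludes ADC outliers (≤ 50 × 10⁻⁶ mm²/s) and classifies every voxel into
   three virtual tissue groups by fixed thresholds (SUV 2.5, ADC 1250):
   *vital* (high SUV, low ADC), *low-vital* (low SUV, high ADC), *equivocal*
   (the other two quadrants);
3. standardizes each tumor dataset to exactly 1000 voxels (subsample or
   bootstrap) and z-normalizes pooled ADC and SUV values;
4. fits a 3-component Gaussian mixture by EM (written in-repo) to the
   normalized data — 2D by default, 1D with intersection-derived demarcation
   thresholds as an alternative — and assigns semantic clusters;
5. reports subvolume proportions, per-cluster ADC–SUV Pearson correlations,
   paired Wilcoxon signed-rank tests (exact enumeration for n ≤ 15),
   point-biserial correlation and linear regression across timepoints.

A phantom generator (`suvadc.phantom`) produces fully synthetic cohorts with
known ground-truth tissue compartments, negative ADC–SUV coupling inside the
vital compartment, PET-grid degradation of the SUV channel, and
therapy-course transforms (response / progression), so every stage can be
validated against generator truth.

## CLI

```sh
# synthetic phantom (writes suv/adc/mask/labels NIfTI volumes)
suvadc phantom generate --seed 1 --out phantom/ --therapy response

# stage by stage
suvadc prepare --suv suv.nii.gz --adc adc.nii.gz --mask mask.nii.gz --out table.csv
suvadc classify --table table.csv --suv-cut 2.5 --adc-cut 1250 --out labeled.csv
suvadc standardize --table table.csv --n 1000 --seed 1 --out std.csv --constants norm.json
suvadc cluster --table std.csv --mode 2d --seed 1 --out clustered.csv --model model.json
suvadc summarize --table table.csv --out stats.json

# whole cohort in one go (phantom recipe or YAML with per-patient paths)
suvadc run --config cohort.yaml --out results/
```

`suvadc run` writes `result.json`, `proportions.csv`, `clusters.csv` and a
human-readable `report.md`; identical config and seeds give byte-identical
results.

## Layout

| module | contents |
| --- | --- |
| `suvadc.phantom` | synthetic cohorts: config, generator, therapy transforms, NIfTI I/O |
| `suvadc.volumes` | `ScalarVolume`/`VOIMask`, NIfTI read/write, grid resampling, pair extraction |
| `suvadc.voxels` | voxel table, outlier filter, volumes, summary statistics |
| `suvadc.tissue` | threshold classification, group proportions, timepoint comparison |
| `suvadc.standardize` | 1000-voxel standardization, pooled z-normalization |
| `suvadc.gmm` | EM mixture fit, Gaussian intersections, demarcation thresholds, cluster assignment |
| `suvadc.stats` | Pearson / point-biserial / OLS / Wilcoxon signed-rank |
| `suvadc.pipeline` | cohort orchestration and reporting |
| `suvadc.cli` | typer CLI |
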