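# oarvar

Multi-observer organ-at-risk (OAR) delineation variability analysis for
radiotherapy contouring studies. Given planar contour stacks drawn by
several observers on several CT scans, the package quantifies interobserver
variability with three complementary endpoints:

- **Volume descriptives** — mean volume, SE, coefficient of variation, and a
  per-observer volume ratio, plus a Friedman rank test for a systematic
  observer effect.
- **ICC** — a three-way mixed-effects variance-component model (patients and
  observers random, scan time fixed, all interactions) fitted by REML; the
  intraclass correlation is the patient-attributable share of the total
  variance, classified into verbal agreement bands.
- **Concordance index (CI)** — pairwise intersection-over-union of
  rasterized observer masks, pooled over all observer pairs and scans.
- **Regional 3D SD** — a median (majority) contour surface over observers,
  the per-vertex SD of observer signed distances, and its averages globally
  and per anatomical sub-region (cranial/caudal caps, landmark-based
  sections, axial quadrants, closed-slice rule).

A fully deterministic synthetic cohort generator (star-shaped organs,
per-observer volume bias and shift, smooth spherical-harmonic surface
noise with region-dependent amplitude) provides ground-truthed input for
every stage, so the whole pipeline is testable without patient data.

## Command line

```bash
# simulate the default study-like cohort (5 observers x 6 patients x
# 2 scans x 7 structures, one organ of one patient excluded -> 410 contours)
oarvar simulate --seed 1 --out cohort.json --truth-out truth.json

# run all endpoints and write CSV tables (+ per-structure PLY meshes)
oarvar analyze cohort.json --out report/ --spacing 1.0 --meshes

# human-readable summary
oarvar report report/
```

`analyze` writes `organ_summary.csv` (volume descriptives),
`endpoints.csv` (ICC + band, CI mean/min/max, global and regional 3D SD,
volume- vs position-dominated discrepancy flags), `pairwise_ci.csv`,
`volumes.csv` and `run_metadata.json` (config hash, seed, versions).
Custom cohorts and analysis settings can be given as YAML (`--config`).

## Python API

```python
from oarvar import (
    default_cohort_config, generate_cohort,   # synthetic cohorts
    load_contour_set, write_contour_set,      # bespoke JSON contour format
    build_volume_table, summarize_organ, friedman_test,
    fit_components, compute_icc, classify_icc,
    rasterize, pairwise_ci,
    compute_median_surface, local_sd, assign_regions, regional_sd,
    run_analysis, AnalysisConfig,
)

cohort, truth = generate_cohort(default_cohort_config(seed=1))
bundle = run_analysis(cohort, AnalysisConfig(in_plane_spacing=1.0), outdir="report")
print(bundle.endpoints)
```

Contours live in a bespoke JSON format (LPS millimetre coordinates, axial
slices, even-odd polygon semantics; canonical key order and 6-decimal
floats so exports are byte-reproducible). `oarvar.rtstruct.load_rtstruct`
adapts DICOM RT Structure Sets into the same data model.

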