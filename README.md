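# metabocurate

Levelled quality-control and curation of plate-structured targeted
metabolomics data — the kind produced by kit-based quantitative assays
(e.g. serum bile-acid panels) run across many 96-well plates, each carrying
cohort samples alongside reference pools (NIST SRM-1950, a study-pool QC,
GoldenWest serum) and blinded analytical replicates.

It is written for analysts who receive a wide concentration export
(samples × analytes, µM, with `<LOD` / `<LLOQ` censoring markers) plus
plate/well annotations, and need an auditable, reproducible path from raw
concentrations to an analysis-ready matrix. Every stage emits an
intermediate "level" artifact so downstream users can re-enter the
workflow at any point.

## The workflow

| Level | Operation |
|---|---|
| 0 | raw concentration export, censoring markers parsed to per-cell flags |
| 2 | cross-plate scaling on reference pools |
| 3 | analyte filters: replicate CV, replicate ICC, censored fraction |
| 4 | LOD/2 imputation; exclusion *flags* (non-fasting, missing BMI, missing medication record) — rows kept |
| 5 | flagged samples removed, blinded replicates averaged, PCA outlier screen, log2 |

**Plate scaling.** For analyte *a* on plate *p*, with reference-pool wells
measured on every plate,

    factor(p, a) = mean_all_plates(ref_a) / mean_plate_p(ref_a)

and every value on the plate is multiplied by it, so per-plate reference
means coincide with the global mean afterwards. Within-plate sample ratios
are untouched.

**Analyte filters** (computed from blinded duplicate/triplicate groups on
the scaled data; all inequalities strict as stated):

- coefficient of variation: per group CV = s/x̄; analyte CV = mean over
  groups; retained if CV < 30%;
- one-way random-effects intraclass correlation
  ICC = (MSB − MSW) / (MSB + (k₀ − 1)·MSW), with the standard unbalanced
  correction k₀ = (N − Σkᵢ²/N)/(g − 1); retained if ICC > 0.6;
- censoring: fraction of cohort cells below the limit of detection;
  retained unless > 40%.

**Censored-value imputation.** Every `<LOD` cell becomes LOD/2 for its
(analyte, plate); `<LLOQ` values are quantifiable and kept as reported.

**PCA outlier screen.** On standardized log2 values, principal components
are selected as the smallest leading set explaining > 90% cumulative
variance; a subject is flagged when its Mahalanobis distance within that
subspace (each score standardized by its own SD) exceeds 7.

**Medication mapping.** Free-text baseline medication strings are
normalized (case, dosage/form tokens), resolved through an offline
brand/generic → ingredient → drug-class dictionary, and OR-aggregated into
per-subject Boolean class flags; unmatched strings are reported, never
dropped.

Because real cohort data of this kind sit behind access control, the
package ships a synthetic-cohort generator (`metabocurate.simulate`) that
reproduces the plate design — 75 cohort wells plus 3 SPQC, 3 NIST,
1 GoldenWest and kit low/mid/high QC wells per plate, blinded duplicates or
triplicates — with log-normal concentrations, multiplicative plate effects,
per-plate detection limits, and *planted* failing analytes and outlier
subjects whose labels are returned as ground truth.

## Worked example

```python
from metabocurate import adni1_params, generate_dataset, run_pipeline, PipelineConfig

params = adni1_params(
    seed=0,
    planted_bad_analytes=(("CA", "HIGH_CV"), ("GCA", "HIGH_CV"), ("TCA", "LOW_ICC"),
                          ("CDCA", "HIGH_CENSORING"), ("GCDCA", "HIGH_CENSORING")),
    planted_outlier_subjects=((50, 12.0), (51, 12.0)),   # 12-SD profile shifts
    nonfasting_fraction=0.02, missing_bmi_count=2,
)
matrix, annotations, truth = generate_dataset(params)
result = run_pipeline(matrix, PipelineConfig.for_preset("adni1"))
for level, info in result.summary["levels"].items():
    print(f"level {level}: {info}")
```

prints

```
level 0: {'samples': 935, 'analytes': 20}
level 2: {'samples': 935, 'analytes': 20}
level 3: {'samples': 935, 'analytes': 15}
level 4: {'samples': 825, 'subjects': 807, 'analytes': 15}
level 5: {'subjects': 787, 'analytes': 15}
```

Reading: 11 plates × 85 wells enter at level 0 (825 cohort injections plus
110 QC wells). Scaling keeps all 20 analytes; the filters remove exactly
the five planted failures (20 → 15); level 4 restricts to cohort
injections and flags 16 non-fasting samples and 2 without BMI; level 5
drops those 18 subjects, averages the 18 blinded duplicate pairs
(807 − 18 = 789 rows) and removes the 2 planted 12-SD outliers, leaving
787 analysis-ready subjects on the log2 scale. The per-analyte filter
statistics and per-sample exclusion reasons are in
`result.artifacts[3].reports["filter_report"]` and
`result.artifacts[4].reports["exclusion_report"]`.

The same run is available from the shell:

```bash
metabocurate simulate --preset adni1 --seed 7 --out sim/
metabocurate run --matrix sim/level0_matrix.csv --annotations sim/annotations.csv \
                 --lods sim/lods.csv --out run/
metabocurate medmap --meds meds.csv --out flags.csv
```

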