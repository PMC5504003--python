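# capiflow

Parafoveal capillary blood-flow velocimetry from adaptive-optics
scanning-laser-ophthalmoscope (AOSLO) video stacks, together with the
clinical statistics used to analyse such measurements in a
glaucoma-treatment study design — plus synthetic-data generators so the
whole chain is testable end to end without any real recordings.

## What it does

**`capiflow.sim`** — synthetic data with known ground truth:

- `simulate_capillary_video` renders 2-second, 64 frames/s grayscale
  stacks (1.4 × 2.8° field) of a single unbranched capillary over a
  photoreceptor-mosaic background. Bright leukocyte plugs trailed by
  dark erythrocyte aggregates advance along the vessel at a
  configurable, optionally pulsatile velocity; exact per-frame plug
  positions are returned.
- `simulate_cohort` draws subject-visit tables (healthy controls at
  baseline; treated glaucoma patients at baseline and weeks 1/4/12)
  with configurable per-visit means/SDs, compound-symmetric
  within-subject correlation, and dropout.
- `simulate_vf_test` builds 24-2 visual-field pattern-deviation maps
  with a prescribed depressed-point configuration and reliability
  indices.

**`capiflow.velocimetry`** — the measurement chain:

1. rigid frame registration (phase correlation),
2. motion-contrast perfusion map (temporal SD / mean),
3. sub-pixel vessel tracing through user seeds (geodesic + ridge
   refinement), with angle-to-retina scaling from the eye's axial
   length (Bennett-style: 0.01306·(AL − 1.82) mm/deg),
4. kymograph (spatiotemporal image: frame × arc length),
5. detection of the anterior edges of the dark bands and robust
   least-absolute-deviation line fits,
6. velocity in mm/s as the reciprocal of the band slope, averaged over
   bands.

On simulated videos across 0.5–3.0 mm/s the full pipeline recovers the
true velocity with mean absolute relative error well under 10 %.

**`capiflow.stats`** — the study's clinical/statistical pipeline:
ocular perfusion pressure (2/3·[dBP + (sBP − dBP)/3] − IOP), logMAR
conversion, Anderson–Patella-style visual-field classification
(reliability cut-offs, hemifield cluster search), unpaired-t/chi-square
baseline comparison, within-subject repeated-measures ANOVA with
Bonferroni-corrected paired post hoc tests and per-subject percent
changes, noncentral-F power analysis / sample-size computation, and a
`run_study` driver that applies eligibility and emits report tables.

## Command line

```bash
# synthetic data
capiflow simulate video  --seed 1 --out video.tiff          # + .json sidecar + .truth.json
capiflow simulate cohort --seed 1 --out cohort.csv
capiflow simulate vf     --config vfspec.json --out vf.json

# measurement: seed points are "row,col" pairs on the vessel
capiflow velocity --video video.tiff --seeds "150,30 150,280" --out out/

# cohort analysis and power
capiflow cohort --cohort cohort.csv --vf vf.json --out report/
capiflow power --f 0.4 --alpha 0.05 --power 0.8 --m 4 --rho 0.5
```

Video stacks are multi-page TIFFs with a JSON sidecar (fps, field size,
axial length); cohorts are CSVs with one row per subject-visit; visual
fields are JSON in a documented 54-point order (`capiflow.vf24`).

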