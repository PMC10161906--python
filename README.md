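# dscqc

Automated quality control for dynamic susceptibility contrast (DSC-) MRI
signal–time courses.

Per voxel, the package segments the bolus first pass out of the dynamic
signal, computes four quantitative quality measures, and predicts pass/fail
quality either from calibrated thresholds or from a trained classifier:

* **SDNR** — signal drop-to-noise ratio: the drop (mean baseline minus the
  mean of the first-pass minimum and its two neighbours) divided by the
  baseline standard deviation.
* **RMSE** — root mean square error of a simplified gamma-variate fit
  `y(t) = c − K·t^α·e^(−t/β)` to the first pass, normalised by the
  trapezoidal area of the drop curve (units 1/s).
* **FWHM** — width of the first pass at half the signal drop, in seconds.
* **PSR** — percentage signal recovery of the post-bolus plateau.

Thresholds are calibrated from binary reviewer labels by stratified k-fold
cross-validation: SDNR/RMSE cut-offs sit where training sensitivity equals
specificity; FWHM/PSR get inclusive ranges spanning the reviewed-and-passed
values. Five classifier families (decision tree, SVM, bagged trees, random
forest, logistic regression) can be trained on the four measures with
nested CV (outer stratified 10-fold, inner 5-fold AUC grid search).
Interrater agreement utilities (percentage disagreement, Cohen's kappa) and
a ground-truth-labelled synthetic signal simulator round out the pipeline,
so everything is testable without patient data.

## Command line

The `dscqc` entry point chains the pipeline stages:

```sh
# labelled synthetic cohort (signals + truth tables)
dscqc simulate --seed 1 --n 300 --signals-out signals.csv --truth-out truth.csv

# four quality measures per course
dscqc extract --signals signals.csv --out features.csv

# threshold calibration by stratified 10-fold CV
dscqc calibrate --features features.csv --labels truth.csv --seed 1 \
    --out thresholds.yaml --metrics-out threshold_metrics.csv

# train all five classifier families, keep the winner
dscqc train --features features.csv --labels truth.csv --seed 1 \
    --model-out model.joblib --report-out comparison.csv

# predictions for a feature table
dscqc predict --features features.csv --model model.joblib --out predictions.csv

# voxel-wise quality map from a 4D NIfTI volume
dscqc simulate --seed 1 --n 20 --signals-out s.csv --truth-out t.csv \
    --phantom-out phantom.nii
dscqc map --volume phantom.nii --method threshold --measures fwhm_s,psr_pct \
    --out qmap.nii

# interrater agreement (CSV with r1, r2 and optional group columns)
dscqc agreement --ratings ratings.csv
```

`dscqc map` accepts `--tr` (overrides the header repetition time, seconds),
`--mask` (3D NIfTI; default is a mean-signal heuristic), and
`--thresholds` (YAML; defaults to the shipped values below).

## Conventions

* Dynamic (time point) indices in reports are 1-based and inclusive;
  spatial voxel indices follow the 0-based array order of the volume.
* The accepted label (1) is the positive class in every metric.
* Quality maps encode 1 = pass, 0 = fail, NaN = excluded (no bolus
  detected, or outside the mask); a JSON sidecar records provenance.

## Shipped default thresholds

`dscqc.default_thresholds()` returns SDNR ≥ 7.6, RMSE ≤ 0.019,
FWHM 3–19 s, PSR 42.9–130.4 %. These were calibrated on one specific
multicentre paediatric cohort and are defaults only — recalibrate with
`dscqc calibrate` for your own data. Synthetic cohort artifact prevalences
(5 % per class) are likewise package defaults with no claim to clinical
frequency.

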