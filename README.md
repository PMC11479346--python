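# vimsdetect

Detection of visually induced motion sickness (VIMS) from multichannel
physiological recordings: sliding-window feature extraction (23 features at
1-second resolution from ECG, respiration, electrodermal activity,
horizontal EOG and 4-channel EEG), baseline-ratio standardisation, binary
severity labelling, gradient-boosted classification with
leave-one-participant-out cross-validation, and normalized-time trend
analysis. A seeded synthetic-signal generator with injected ground truth
makes every stage testable without access to clinical recordings.

## Layout

| module | role |
| --- | --- |
| `vimsdetect.recordings` | domain types (`Recording`, `ChannelSignal`, `ReportEvent`), `PipelineConfig`, plain-text session I/O |
| `vimsdetect.synthdata` | `ScenarioConfig`/`simulate_session`/`simulate_cohort`: multichannel signal simulator with a latent severity curve and per-modality effect sizes |
| `vimsdetect.features` | R-peak detection, HR spectral features (LF/HF), respiration period, SCL/SCR decomposition, saccade detection, EEG band ratios/peak frequencies, lambda-response (eye-fixation-related potential), and `extract_features` producing the 23-column 1-Hz table |
| `vimsdetect.preprocess` | per-second label series (update-and-hold, level-5 truncation), baseline-ratio standardisation (mean of the 90 rows in the first 120 s), pooled 1/99-percentile clipping with previous-value repair, dataset assembly |
| `vimsdetect.model` | Newton-boosted tree ensemble (`lambda_l1`, `lambda_l2`, `num_leaves`, `feature_fraction`, `bagging_fraction`, `bagging_freq`, `min_child_samples` with native semantics), stepwise seeded tuner (stratified 5-fold ROC-AUC, class weights `n/(2*n_class)`), grouped LOOCV |
| `vimsdetect.evaluation` | accuracy / Cohen's kappa / ROC-AUC / PR-AUC (average precision), recall-precision at threshold, 1000-segment normalized-time trends with 95% CIs and feature-severity correlations |

## CLI

```bash
vimsdetect --seed 7 simulate --n 9 --out recordings/ --duration 600
vimsdetect extract --in recordings/ --out features.csv
vimsdetect standardize --features features.csv --labels features_labels.csv \
    --out dataset.csv --thresholds thresholds.csv
vimsdetect --seed 7 train --dataset dataset.csv --out model_dir/
vimsdetect --seed 7 evaluate --dataset dataset.csv --report report.csv \
    --predictions preds.csv
vimsdetect trends --dataset dataset.csv --predictions preds.csv \
    --out trends.csv --summary trend_summary.csv
```

All artefacts are comma-separated text with header rows; recordings are
directories of per-channel CSV files plus `events.csv` / `metadata.json`
(lossless float round-trip). A `--config cfg.yaml` option on the group
overrides any `PipelineConfig` key.

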