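# emg2prosody

Prediction of continuous voice fundamental-frequency (f0) and intensity
contours from 8-channel facial/neck surface EMG.  The package implements the
full processing chain — synthetic session generation, EMG-to-audio alignment
by exact dynamic time warping, acoustic target extraction (autocorrelation
f0 tracking and Kaiser-smoothed intensity with dB SPL calibration), a
20-family per-frame EMG feature battery, PCA-based dimensionality reduction
with stratified splitting and Gaussian augmentation, deep feed-forward
regression, and concordance-based evaluation.

Because no public recordings exist for this task, the `synthgen` module
produces fully synthetic sessions in which per-channel muscle-activation
envelopes are statistically coupled to known f0/intensity trajectories, so
every downstream stage can be exercised and verified end-to-end.

## Layout

| module            | role                                                      |
|-------------------|-----------------------------------------------------------|
| `signals`         | `SignalTrack` / `Contour` carrier types                   |
| `io`              | WAV, delimited contour, and columnar EMG I/O              |
| `synthgen`        | synthetic sessions with known ground truth                |
| `acoustics`       | f0 tracker, intensity contour, SPL calibration, semitones |
| `align`           | envelope features, exact full/low-memory DTW, warping     |
| `emgfeat`         | per-frame EMG feature battery (516 features / 8 channels) |
| `mlprep`          | stratified split, augmentation, PCA, k-fold assignment    |
| `regressor`       | numpy MLP (GeLU, Adam, early stopping), target transforms |
| `evalmetrics`     | MAPE, Pearson r, Lin CCC, RMSE, MBE; fold selection       |
| `pipeline` / `cli`| stage runner with manifests; `emg2prosody` console script |

## CLI

Stages run individually or as a chain, all driven by a YAML config and a
mandatory seed:

```sh
emg2prosody run --seed 1 --out run/            # simulate ... evaluate
emg2prosody simulate --config exp.yaml
emg2prosody train --config exp.yaml
emg2prosody report run/
```

Each stage writes a manifest (config hash, derived stage seed, realized
dimensions) under `<out>/manifests/`; reruns with the same config are
byte-identical.

Example config:

```yaml
seed: 1
out_dir: run
sessions:
  speaker_seed: 1
  tasks: {tone: 4, legato: 2, phrase: 6, passage: 4, question: 2, monologue: 2}
k_folds: 5
pca_variance: 0.90
augment_scale: 0.1
model:
  max_epochs: 60
  hidden_layers: [256, 128]
  dtype: float32
```

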