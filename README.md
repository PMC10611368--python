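# drowsyfuse

A toolkit for multi-sensor driver-fatigue recognition from physiological
signals, with a real-time mode-fusion feedback engine. The pipeline is
fully exercisable end-to-end on synthetic data — no external dataset
downloads are required.

Components:

- **synthgen** — synthetic EEG (band-weighted filtered noise), ECG
  (PQRST Gaussian-bump trains with controllable RR statistics), scripted
  4-row label streams, and trivially separable fixture images. Every
  generator is deterministic given its seed.
- **sigio** — signal containers, CSV/NPZ I/O, epoching, feature tables,
  YAML run configuration.
- **preprocess** — zero-phase Butterworth filtering: EEG 0.15–40 Hz
  band-pass + 50 Hz notch; ECG 0.1–30 Hz band-pass + linear detrend.
- **eeg_features** — per-channel band powers (delta/theta/alpha/beta via
  Welch PSD area) and four entropies (sample, approximate, fuzzy,
  spectral), 8 features per channel.
- **ecg_features** — R-peak detection by normalized matched filtering
  with a 15-tap sinusoid kernel, RR intervals, and five HRV statistics
  (RMSSD, AVRR, SDRR, skewness, excess kurtosis).
- **classify** — gradient-boosted-tree fatigue classifier (plus SVM and
  logistic-regression comparators) with stratified 80/20 splitting,
  evaluation reports, and feature importances.
- **distraction_cnn** — a pure-numpy CNN (32/64/128 3×3 conv blocks,
  two max-poolings, 128/64 dense layers, 192-unit softmax output) with
  Adam and sparse categorical cross-entropy.
- **fusion** — append-only 4-row label matrix, 5 s sliding window with
  1 s stride, per-row modes, pattern-dictionary severity lookup, and a
  persistence threshold before severe/mild alerts are raised.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (worked fusion
example, dictionary mappings, CNN architecture, entropy brute-force
oracle equivalence, HRV hand checks, R-peak recovery, filter tone tests,
end-to-end classification of synthetic presets, fusion persistence).

## CLI

```sh
# synthetic fixtures
drowsyfuse simulate eeg --out scratch/sim --seed 1 --state fatigued --duration 60
drowsyfuse simulate ecg --out scratch/sim --seed 1 --duration 60
drowsyfuse simulate labels --out scratch/sim --segment 10:1,3,4,7 --segment 5:0,2,4,6
drowsyfuse simulate images --out scratch/imgs --n-per-class 10 --size 64

# feature extraction (preprocess -> epoch -> features)
drowsyfuse extract eeg --in scratch/sim/eeg_fatigued_1.csv --fs 128 \
    --channels P3,P4 --out scratch/eeg_features.csv
drowsyfuse extract ecg --in scratch/sim/ecg_1.csv --fs 256 \
    --out scratch/hrv_features.csv --peaks-out scratch/peaks.json

# classification
drowsyfuse train --features scratch/eeg_features.csv --backend gbdt \
    --seed 1 --out scratch/model.bin --report scratch/report.json

# fusion feedback
drowsyfuse fuse --labels scratch/sim/labels_0.csv --persist 3 \
    --out scratch/results.jsonl
```

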