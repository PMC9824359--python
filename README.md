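# repscore

Automatic ordinal quality scoring ("1" / "2" / "3") of single exercise
repetitions recorded by a body-worn network of inertial measurement units
(default: 17 IMUs x 6 channels — triaxial accelerometer in g and gyroscope
in °/s — at 120 Hz), using CNN-LSTM models that handle variable-length
repetitions through zero-padding, equal-width windowing and masked
recurrence.

The package covers the full pipeline:

| module | role |
| --- | --- |
| `repscore.core` | domain types (`ChannelLayout`, `Repetition`, `Dataset`), on-disk dataset storage and validation |
| `repscore.synthetic` | seeded synthetic dataset generator (class-dependent deviation bursts, subject idiosyncrasies, sensor noise, noisy three-rater scoring) |
| `repscore.labeling` | Krippendorff's alpha (ordinal / nominal / interval, coincidence-matrix formulation), three-rater majority vote, agreement summaries |
| `repscore.alignment` | sensor-to-segment rotation composition and application |
| `repscore.preprocess` | channel stacking, per-modality standardization, zero-padding, windowing, per-window validity masks, per-IMU input variant |
| `repscore.models` | the three CNN-LSTM variants (baseline, IMU-centric, channel-centric), block resolution, layer inventories |
| `repscore.evaluation` | stratified shuffle splits (64/16/20), Monte-Carlo CV, leave-one-subject-out folds, per-class / macro / weighted F1 |
| `repscore.workbench` | training loop (Adam, categorical cross-entropy, early stopping), CV / LOSO runners, seeded random hyperparameter search |
| `repscore.nn` | minimal NumPy layer library with hand-derived backprop (conv2d, max-pool, dropout, batch-norm, masked LSTM, dense, Adam) — no deep-learning framework is required at runtime |

## CLI

```bash
# generate a labeled synthetic dataset (movement + simulated raters)
repscore generate --out data/demo --seed 1 --n-subjects 5 --reps-per-subject 10 \
    --n-imus 4 --duration-range 1.5,2.5 --sampling-rate 30 --affected-segments 2

# resolve rater scores by majority vote + reliability report
repscore labels --dataset data/demo --out data/demo_agreement.tsv

# fit preprocessing (standardization + windowing) and record the manifest
repscore preprocess --dataset data/demo -x 10 --out data/demo_preprocess.json

# inspect an architecture
repscore describe --variant baseline --n-blocks 3 --input-shape 10,102,12

# train / cross-validate / LOSO / hyperparameter sweep
repscore train  --dataset data/demo --seed 1 --out runs/train.json
repscore cv     --dataset data/demo --seed 1 --n-folds 5 --out runs/cv.json
repscore losocv --dataset data/demo --seed 1 --n-folds 3 --out runs/loso.json
repscore sweep  --dataset data/demo --seed 1 --n-runs 90 --out runs/sweep.json
```

All runs are reproducible from their seeds; every artifact records the seeds
used.

## Dataset directory format

A dataset is a directory with a `manifest.json` plus one `.npy` array file
per repetition. The manifest records the channel layout (IMU order, 6
channels per IMU: accel x/y/z then gyro x/y/z, so channel `c` of IMU `k` is
row `6k + c`), the label map (`1/2/3` to class indices `0/1/2`), creation
metadata (generator config and seed for synthetic data), and an index entry
per repetition (id, subject, exercise, side, sampling rate, rater scores,
resolved label, file name, array shape). Arrays are `(n_channels, T)` with
variable `T`; units are as recorded (g, °/s). `repscore.core.
export_repetition_csv` writes a delimited-text view of one repetition for
inspection.
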