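# rhythmnet

Automatic rhythm classification of single-lead ECG recordings into four
classes — normal sinus rhythm (`N`), atrial fibrillation (`A`), other rhythm
(`O`) and noisy (`~`) — for anyone studying arrhythmia screening on
ambulatory or handheld ECG devices.

The pipeline combines:

- **Denoising**: wavelet decomposition to level 9 with universal-threshold
  shrinkage (`σ√(2 ln n)`, σ from the finest detail level's MAD/0.6745),
  followed by median-filter baseline removal (the signal minus its running
  median, so sub-Hz electrode drift is subtracted out).
- **A deep 1-D CNN + BiLSTM classifier**: 24 same-padded convolutions of
  kernel width 16 (three 8-layer blocks of 32/64/128 filters, each conv
  followed by batch norm, ReLU and dropout, max-pool 2/2 after every two
  convs), a BiLSTM-64 then BiLSTM-128 whose forward/backward states are
  concatenated (h_t = h⃗_t ⊕ h⃖_t), and a 128/64/32/4 dense head with
  softmax.
- **The TMSE loss**: the mean over elements of the tangent of the squared
  residual,

      TMSE = (1/N) Σᵢ tan((yᵢ − ŷᵢ)²),

  with squared residuals clamped to [0, 1] so the map stays inside tan's
  first branch. Since tan s ≥ s on [0, π/2), TMSE dominates MSE and reduces
  to it for small residuals; its gradient is −2(y − ŷ)·sec²((y − ŷ)²)/N.
- **Evaluation**: 4×4 confusion matrix, per-class precision/recall/F1
  (F1 = 2PR/(P+R)), accuracy, and overall F1 under both the three-class
  (N/A/O, the CinC 2017 convention) and four-class means.
- **An ablation harness** over five configurations (WT-TMSE, MT-TMSE,
  WT-MT-CEEF, WT-MT-MSE, WT-MT-TMSE) with stratified 90/10 hold-out and
  ten-fold cross-validation.
- **A synthetic ECG generator** (sum-of-Gaussians P-QRS-T beats, per-class
  RR-interval statistics, controllable wander/powerline/broadband/impulse
  noise) so the entire pipeline runs and is tested without downloading any
  data. Real recordings in the PhysioNet/CinC 2017 layout (`.mat` + `.hea`,
  300 Hz) are supported through `rhythmnet.io`, including the ≥ 9000-sample
  record-length filter applied before training.

The neural network runs on a small bundled numpy engine (convolution,
batch norm, dropout, max pooling, bidirectional LSTM, dense, softmax, Adam —
all with hand-written backward passes), so there is no GPU-framework
dependency; see `docs/methods.md` for design details and limitations.

## Worked example

```python
import numpy as np
from rhythmnet import (
    SyntheticDatasetSpec, generate_dataset,
    DenoiseConfig, denoise_pipeline, snr_db,
    PredictionBatch, tmse_loss, mse_loss,
)
from rhythmnet.experiment import run_experiment, scaled_config

# 100 labelled synthetic records, 25 per class, with ambulatory noise
spec = SyntheticDatasetSpec(records_per_class=25, duration_range=(9.0, 31.0),
                            master_seed=0)
records, manifest = generate_dataset(spec)
print("records:", len(records), "counts:", manifest["label"].value_counts().to_dict())

# denoise one record and measure the SNR gain against the known clean signal
rec = records[0]
out = denoise_pipeline(rec.samples,
                       DenoiseConfig(median_window=241, threshold_levels=(1, 2, 3)))
clean = rec.meta["clean"]
print(f"SNR before {snr_db(clean, rec.samples):.1f} dB -> after {snr_db(clean, out):.1f} dB")

# TMSE always dominates MSE
batch = PredictionBatch(np.eye(4)[[0, 1, 2]],
                        np.array([[0.7, 0.1, 0.1, 0.1],
                                  [0.2, 0.6, 0.1, 0.1],
                                  [0.25, 0.25, 0.25, 0.25]]))
print(f"TMSE {tmse_loss(batch):.4f} >= MSE {mse_loss(batch):.4f}")

# desk-scale end-to-end run: denoise, 90/10 split, train 10 epochs, evaluate
result = run_experiment(scaled_config(seed=0, epochs=10), records)
agg = result.aggregate
print(f"hold-out accuracy {agg.accuracy:.3f}; overall F1 (N/A/O) {agg.overall_f1_nao:.3f}")
```

Output:

```
records: 100 counts: {'N': 25, 'A': 25, 'O': 25, '~': 25}
SNR before 0.9 dB -> after 9.2 dB
TMSE 0.0967 >= MSE 0.0908
hold-out accuracy 0.700; overall F1 (N/A/O) 0.690
```

The first line confirms the balanced synthetic dataset; the second shows the
combined wavelet + median pipeline lifting a record corrupted to ~1 dB SNR
by about 8 dB; the third illustrates the tan-domination property of the
loss; the last is a real training run of the six-convolution desk-scale
network (chance accuracy is 0.25). A larger run — 100 records per class —
typically lands between 0.65 and 0.90 hold-out accuracy depending on the
seed.

## Command line

```sh
rhythmnet simulate --per-class 25 --seed 1 --out data/     # write .mat/.hea pairs
rhythmnet denoise data/SN000000 --out denoised/ --median-window 241
rhythmnet summary                                          # audit the layer table
rhythmnet train --data data/ --ablation WT-MT-TMSE --mode holdout --out run/
rhythmnet evaluate --run run/
rhythmnet ablation --data data/ --out run/                 # five-row comparison table
```

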