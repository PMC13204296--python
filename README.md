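# tckey

Temporal-contextual decoding of character-level keystrokes from multichannel
surface EMG. The package implements the complete pipeline — window
segmentation, band-pass filtering, noise/channel-dropout augmentation,
per-channel normalization, stratified splitting, a dilated-causal-convolution
+ transformer-encoder classifier with its ablation variants, the training
loop (Adam, gradient clipping, plateau scheduling, best-epoch selection), and
an evaluation battery (confusion analysis, per-class precision/recall/F1,
one-vs-rest ROC/AUC, confidence and calibration analysis, confused-pair
mining, group-wise accuracy with one-way ANOVA, pooled-embedding PCA) —
backed by a synthetic keystroke-EMG generator so everything is testable
without external data.

The neural network runs on a small numpy reverse-mode autodiff engine
(`tckey.nn`) written for this package, so no deep-learning framework is
required.

## Test

```bash
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, which trains several small
models; the full run takes roughly 10–15 minutes on one CPU. Everything else
finishes in well under a minute.

## CLI

One entry point, five subcommands, each writing a `manifest.json` capturing
the resolved configuration, seed, and paths:

```bash
# 1. synthesize a labeled window store
tckey synth --n-classes 6 --n-channels 8 --reps-per-class 40 \
    --snr-db 20 --seed 42 --out runs/raw.npz

# 2. band-pass filter, augment x3 (sigma 0.01, one dropped channel/copy), normalize
tckey preprocess --windows runs/raw.npz --out runs/prep.npz --seed 42

# 3. train the full variant (stratified 80:20 split)
tckey train --windows runs/prep.npz --out-dir runs/full --variant full \
    --epochs 30 --lr 2e-3 --seed 42

# 4. evaluation battery -> JSON/CSV report
tckey evaluate --checkpoint runs/full/model.npz --windows runs/prep.npz \
    --report-dir runs/full/report

# 5. train all four ablation variants on the same split/seed
tckey ablate --windows runs/prep.npz --out-dir runs/ablation --seed 42
```

Window stores are NPZ (or HDF5 via a `.h5` extension) containers with a JSON
manifest sidecar; checkpoints are NPZ weight files with an architecture JSON
sidecar.

## Model variants

| variant | stages |
| --- | --- |
| `baseline_cnn` | plain conv blocks → mean-pool → linear head |
| `temporal_only` | dilated causal blocks (d=2, 4) → mean-pool → head |
| `transformer_only` | linear projection → positional encoding → encoder → head |
| `full` | dilated causal blocks → projection → encoder → head |

The published hyperparameter set fixes the transformer stage exactly but not
the temporal front-end. `tckey.model.reconcile_reference_config` enumerates
front-end configurations (block count, channel widths, kernel, stride, bias
and norm-affine options) and pins the first whose full-model trainable
parameter count equals the published 849,818: two causal blocks
(16→16 at dilation 2, 16→128 at dilation 4), kernel 4, strides (1, 2),
bias-free convolutions, non-affine batch-norm, learned positional table of
length 200. Note the same total is also reached by the transformer-only
stack on the raw 16×400 input with a 400-step positional table, which may be
the origin of the published figure; both reconciliations are available in
code.
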