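# neuroage

Brain-age prediction from 3D T1-weighted volumes with a NumPy-native deep
regression stack. The package covers the full pipeline at desk scale:

- **phantom** — synthetic registered brain phantoms whose ventricle size and
  cortical shell thickness encode age (and, optionally, sex-dependent aging
  trajectories), plus the rigid rotation/translation training augmentation.
- **io_preproc** — NIfTI-1 I/O, isotropic cubic-spline resampling (default
  1.5 mm, production grid 105×127×105) and foreground intensity z-scoring.
- **model** — three predictor variants: a 3D CNN fused with an MLP sex branch
  (`cnn_mlp`), the image-only CNN (`cnn_only`), and a CNN with a single linear
  sex layer (`cnn_linear_sex`). Conv blocks are conv3×3×3 → batch norm → ReLU
  → max-pool /2 with channel doubling from 8.
- **training** — MSE training with Adagrad/Adam/NAG/RMSprop/SGD and
  inverse-time learning-rate decay, age-stratified splits, k-fold
  cross-validation (default 10), the 5×2 optimizer/lr/decay grid search, and
  MAE/RMSE/R² metrics.
- **bias** — linear bias correction: OLS of the brain-age gap on chronological
  age, offset subtracted from predictions.
- **attention** — Grad-CAM adapted to scalar regression: per-subject maps,
  global averages, and male-minus-female difference maps.
- **stats** — brain-age gap and pooled-variance independent t-tests, from raw
  gaps or from printed (n, mean, SD) summaries.

The network engine (3D convolution, batch norm, pooling, dense layers,
backprop, optimizers) is implemented in NumPy so the package runs on a plain
CPU-only scientific Python installation; all gradients are finite-difference
checked in the test suite.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end acceptance criteria
(worked-statistic reproduction, metric/bias identities, architecture shape
oracle, phantom age recovery, sex-fusion benefit, Grad-CAM localization,
t-test calibration). The full suite takes a few minutes on one CPU; the
phantom training criteria dominate.

## CLI

One entry point with subcommands; every run writes a `manifest.json`
reproducibility record next to its outputs.

```sh
neuroage simulate --n 120 --age-range 20,88 --grid 16,16,16 --seed 1 --out cohort/
neuroage preprocess --in raw.nii.gz --out prep.nii.gz --spacing 1.5 --shape 105,127,105
neuroage train --table cohort/cohort.csv --variant cnn_mlp --epochs 30 --seed 1 --out model.npz
neuroage cv --table cohort/cohort.csv --k-folds 10 --out cv.csv
neuroage grid --table cohort/cohort.csv --out grid.csv
neuroage predict --model model.npz --table cohort/cohort.csv --out pred.csv
neuroage bias-fit --pred-table pred.csv --out-model bias.json
neuroage bias-apply --model bias.json --pred-table pred.csv --out corrected.csv
neuroage attention --model model.npz --cohort cohort/cohort.csv --out-dir maps/
neuroage compare --table gaps.csv --group-col diagnosis
```

Training options can also come from a YAML config (`--config`), mirroring
`TrainConfig`/`ModelSpec` field names; flags override file values.

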