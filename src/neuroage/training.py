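"""Training loop, metrics, stratified splitting, k-fold CV, optimizer grid."""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .model import ModelSpec, Predictor, build_model, records_to_arrays
from .nn.optim import OPTIMIZERS, make_optimizer
from .phantom import AugmentConfig, augment
from .types import SubjectRecord, VolumeImage

#: the optimizer/hyperparameter search grid: 5 optimizers x 2 (lr, decay)
GRID_LR_DECAY = ((0.01, 0.003), (0.001, 0.0003))


class TrainingDiverged(RuntimeError):
    pass


@dataclass
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 0.001
    decay: float = 0.0003
    batch_size: int = 16
    epochs: int = 30
    k_folds: int = 10
    augment: AugmentConfig | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optimizer.lower() not in OPTIMIZERS:
            raise ValueError(
                f"unknown optimizer {self.optimizer!r}; choose from {sorted(OPTIMIZERS)}"
            )
        self.optimizer = self.optimizer.lower()
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


@dataclass
class Metrics:
    mae: float
    rmse: float
    r2: float

    def as_dict(self) -> dict:
        return {"mae": self.mae, "rmse": self.rmse, "r2": self.r2}


@dataclass
class CVReport:
    folds: list[Metrics]
    fold_predictions: list[np.ndarray] = field(default_factory=list)
    fold_indices: list[np.ndarray] = field(default_factory=list)

    @property
    def mean(self) -> Metrics:
        return Metrics(
            mae=float(np.mean([f.mae for f in self.folds])),
            rmse=float(np.mean([f.rmse for f in self.folds])),
            r2=float(np.mean([f.r2 for f in self.folds])),
        )

    @property
    def std(self) -> Metrics:
        return Metrics(
            mae=float(np.std([f.mae for f in self.folds])),
            rmse=float(np.std([f.rmse for f in self.folds])),
            r2=float(np.std([f.r2 for f in self.folds])),
        )


def compute_metrics(y_true, y_pred) -> Metrics:
    """MAE, RMSE and R^2 (SS_tot about the mean of ``y_true``)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or y_true.size == 0:
        raise ValueError(
            f"y_true and y_pred must be equal-length nonempty vectors, got "
            f"{y_true.shape} and {y_pred.shape}"
        )
    err = y_pred - y_true
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("y_true has zero variance; R^2 is undefined")
    r2 = 1.0 - float(np.sum(err**2)) / ss_tot
    return Metrics(mae=mae, rmse=rmse, r2=r2)


def _age_bins(records, bin_width: float):
    bins: dict[int, list[int]] = {}
    for i, r in enumerate(records):
        bins.setdefault(int(math.floor(r.age / bin_width)), []).append(i)
    return bins


def stratified_split(
    records: list[SubjectRecord],
    test_fraction: float,
    age_bin_width: float = 5.0,
    seed: int = 0,
) -> tuple[list[SubjectRecord], list[SubjectRecord]]:
    """Age-stratified train/test split; disjoint and exhaustive."""
    if not records:
        raise ValueError("cannot split an empty cohort")
    if not 0.0 <= test_fraction <= 1.0:
        raise ValueError("test_fraction must be in [0,1]")
    rng = np.random.default_rng(seed)
    test_idx: set[int] = set()
    for _, members in sorted(_age_bins(records, age_bin_width).items()):
        members = list(members)
        rng.shuffle(members)
        n_test = int(round(test_fraction * len(members)))
        test_idx.update(members[:n_test])
    train = [r for i, r in enumerate(records) if i not in test_idx]
    test = [r for i, r in enumerate(records) if i in test_idx]
    return train, test


def stratified_fold_indices(
    records: list[SubjectRecord], k: int, age_bin_width: float = 5.0, seed: int = 0
) -> list[np.ndarray]:
    """K disjoint exhaustive folds, age-stratified by round-robin in bins."""
    if k > len(records):
        raise ValueError(f"k_folds={k} exceeds cohort size {len(records)}")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    cursor = 0
    for _, members in sorted(_age_bins(records, age_bin_width).items()):
        members = list(members)
        rng.shuffle(members)
        for idx in members:
            folds[cursor % k].append(idx)
            cursor += 1
    return [np.asarray(sorted(f), dtype=int) for f in folds]


def train(
    spec: ModelSpec, train_records: list[SubjectRecord], config: TrainConfig
) -> tuple[Predictor, list[float]]:
    """Fit a predictor with MSE loss on standardized ages.

    Deterministic for a fixed ``config.seed``. Augmentation (when
    configured) is applied per sample per epoch during training only.
    Returns the model plus a per-epoch mean-loss history.
    """
    if not train_records:
        raise ValueError("training set is empty")
    vols, sexes, ages = records_to_arrays(train_records, spec.input_shape)

    model = build_model(spec, init_seed=config.seed)
    y_mean = float(ages.mean())
    y_std = float(ages.std()) or 1.0
    model.y_mean, model.y_std = y_mean, y_std
    model.fingerprint = {
        "init_seed": config.seed,
        "optimizer": config.optimizer,
        "learning_rate": config.learning_rate,
        "decay": config.decay,
        "batch_size": config.batch_size,
        "epochs": config.epochs,
        "n_train": len(train_records),
    }
    y = (ages - y_mean) / y_std

    opt = make_optimizer(config.optimizer, config.learning_rate, config.decay)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(1,)))
    history: list[float] = []
    n = len(train_records)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = vols[idx]
            if config.augment is not None and config.augment.probability > 0:
                xb = np.stack(
                    [
                        augment(
                            VolumeImage(xb[j], spacing=(1.5, 1.5, 1.5)),
                            config.augment,
                            draw_seed=int(rng.integers(2**31)),
                        ).data
                        for j in range(len(idx))
                    ]
                )
            pred = model.forward(
                xb, sexes[idx] if model.uses_sex() else None, training=True, rng=rng
            )
            err = pred - y[idx]
            loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise TrainingDiverged(
                    f"loss became non-finite at epoch {epoch} "
                    f"(optimizer={config.optimizer}, lr={config.learning_rate})"
                )
            losses.append(loss)
            model.backward(2.0 * err / len(idx))
            opt.step(model.parameters())
        history.append(float(np.mean(losses)))
    if config.epochs > 0:
        _recalibrate_batchnorm(model, vols, sexes, rng)
    return model, history


def _recalibrate_batchnorm(model, vols, sexes, rng, cap: int = 256) -> None:
    """Re-estimate BN running statistics on the training set.

    Exponential running averages lag the weights, which at small batch
    sizes and few epochs leaves evaluation-mode normalization far from
    the statistics the trained weights expect. One full-batch forward
    pass with momentum 1 pins each layer's running stats to the
    training-set statistics (dropout stays off: no rng is passed).
    """
    from .nn.layers import BatchNorm

    n = len(vols)
    idx = np.arange(n) if n <= cap else rng.choice(n, size=cap, replace=False)
    bns = [l for l in model.all_layers() if isinstance(l, BatchNorm)]
    saved = [bn.momentum for bn in bns]
    for bn in bns:
        bn.momentum = 1.0
    try:
        model.forward(
            vols[idx], sexes[idx] if model.uses_sex() else None, training=True
        )
    finally:
        for bn, m in zip(bns, saved):
            bn.momentum = m


def evaluate(model: Predictor, records: list[SubjectRecord]) -> Metrics:
    from .model import predict

    pred = predict(model, records)
    return compute_metrics([r.age for r in records], pred)


def crossvalidate(
    spec: ModelSpec, records: list[SubjectRecord], config: TrainConfig
) -> CVReport:
    """K-fold CV (age-stratified folds); per-fold metrics plus mean/sd."""
    from .model import predict

    folds = stratified_fold_indices(records, config.k_folds, seed=config.seed)
    report = CVReport(folds=[])
    for k, test_idx in enumerate(folds):
        test_set = [records[i] for i in test_idx]
        train_set = [r for i, r in enumerate(records) if i not in set(test_idx)]
        fold_cfg = replace(config, seed=config.seed + 1000 * k)
        model, _ = train(spec, train_set, fold_cfg)
        pred = predict(model, test_set)
        report.folds.append(compute_metrics([r.age for r in test_set], pred))
        report.fold_predictions.append(pred)
        report.fold_indices.append(test_idx)
    return report


def optimizer_grid(
    spec: ModelSpec,
    records: list[SubjectRecord],
    base_config: TrainConfig,
    grid: tuple = GRID_LR_DECAY,
    optimizers: tuple = tuple(sorted(OPTIMIZERS)),
) -> dict[tuple[str, float, float], CVReport]:
    """Cross-validate every (optimizer, lr, decay) cell of the grid."""
    table: dict[tuple[str, float, float], CVReport] = {}
    for name in optimizers:
        for lr, decay in grid:
            cfg = replace(base_config, optimizer=name, learning_rate=lr, decay=decay)
            try:
                table[(name, lr, decay)] = crossvalidate(spec, records, cfg)
            except TrainingDiverged as exc:
                raise TrainingDiverged(
                    f"grid cell (optimizer={name}, lr={lr}, decay={decay}): {exc}"
                ) from exc
    return table


def best_grid_row(table: dict) -> tuple:
    """Grid key with the lowest mean CV MAE."""
    return min(table, key=lambda k: table[k].mean.mae)
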