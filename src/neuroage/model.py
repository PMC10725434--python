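"""Predictor architectures: image CNN with optional sex-fusion branches.

Three variants share one image path (stacked conv blocks of
conv3x3x3 -> batch norm -> ReLU -> max pool /2, channels doubling from
``base_channels``, then flatten -> dense(64) -> ReLU -> batch norm ->
dropout -> dense(16) -> ReLU):

- ``cnn_mlp``: a dense(16)/dense(4) ReLU branch embeds the one-hot sex
  label; its output is concatenated with the image features before the
  dense(4) -> dense(1, linear) head.
- ``cnn_only``: the head consumes image features alone; sex is ignored.
- ``cnn_linear_sex``: the raw one-hot sex label is appended to the image
  features and a single linear dense(1) layer produces the age.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .nn.layers import (
    BatchNorm,
    Conv3D,
    Dense,
    Dropout,
    Flatten,
    MaxPool3D,
    ReLU,
    parameters,
)
from .types import SubjectRecord, sex_onehot

VARIANTS = ("cnn_mlp", "cnn_only", "cnn_linear_sex")


@dataclass
class ModelSpec:
    """Architecture hyperparameters selecting among the three variants."""

    variant: str = "cnn_mlp"
    input_shape: tuple[int, int, int] = (105, 127, 105)
    n_conv_blocks: int = 5
    base_channels: int = 8
    dense_image_units: tuple[int, int] = (64, 16)
    dropout_rate: float = 0.3
    mlp_sex_units: tuple[int, int] = (16, 4)
    head_units: tuple[int, int] = (4, 1)
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        self.input_shape = tuple(int(n) for n in self.input_shape)
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError(f"dropout_rate must be in [0,1), got {self.dropout_rate}")
        if self.head_units[-1] != 1:
            raise ValueError("final head layer must have exactly 1 unit")
        self.conv_output_shape()  # validates spatial dims

    def conv_output_shape(self) -> tuple[int, int, int]:
        """Spatial shape after ``n_conv_blocks`` rounds of floor-halving."""
        shape = list(self.input_shape)
        for b in range(self.n_conv_blocks):
            for a in range(3):
                shape[a] = shape[a] // 2
                if shape[a] < 1:
                    raise ValueError(
                        f"input axis {a} ({self.input_shape[a]}) collapses below 1 "
                        f"voxel at conv block {b + 1}; reduce n_conv_blocks"
                    )
        return tuple(shape)

    def block_channels(self) -> list[int]:
        return [self.base_channels * 2**k for k in range(self.n_conv_blocks)]

    def n_flat_features(self) -> int:
        return self.block_channels()[-1] * int(np.prod(self.conv_output_shape()))


class Predictor:
    """A (possibly trained) model instance.

    ``forward`` operates in standardized-age space; :meth:`predict_ages`
    maps back to years using the target mean/sd recorded at training
    time (identity for an untrained model).
    """

    def __init__(self, spec: ModelSpec, init_seed: int = 0):
        self.spec = spec
        self.init_seed = int(init_seed)
        self.fingerprint: dict = {"init_seed": self.init_seed}
        self.y_mean = 0.0
        self.y_std = 1.0
        dtype = np.dtype(spec.dtype).type
        rng = np.random.default_rng(init_seed)

        layers = []
        self.block_relu_idx: list[int] = []
        c_prev = 1
        for c in spec.block_channels():
            layers += [
                Conv3D(c_prev, c, rng=rng, dtype=dtype),
                BatchNorm(c, dtype=dtype),
                ReLU(),
                MaxPool3D(),
            ]
            self.block_relu_idx.append(len(layers) - 2)
            c_prev = c
        u1, u2 = spec.dense_image_units
        layers += [
            Flatten(),
            Dense(spec.n_flat_features(), u1, rng=rng, dtype=dtype),
            ReLU(),
            BatchNorm(u1, dtype=dtype),
            Dropout(spec.dropout_rate),
            Dense(u1, u2, rng=rng, dtype=dtype),
            ReLU(),
        ]
        self.image_layers = layers
        self.n_image_features = u2

        if spec.variant == "cnn_mlp":
            s1, s2 = spec.mlp_sex_units
            self.sex_layers = [
                Dense(2, s1, rng=rng, dtype=dtype),
                ReLU(),
                Dense(s1, s2, rng=rng, dtype=dtype),
                ReLU(),
            ]
            head_in = u2 + s2
        elif spec.variant == "cnn_linear_sex":
            self.sex_layers = []
            head_in = u2 + 2
        else:
            self.sex_layers = []
            head_in = u2

        if spec.variant == "cnn_linear_sex":
            self.head_layers = [Dense(head_in, 1, rng=rng, dtype=dtype)]
        else:
            h1, h2 = spec.head_units
            self.head_layers = [
                Dense(head_in, h1, rng=rng, dtype=dtype),
                ReLU(),
                Dense(h1, h2, rng=rng, dtype=dtype),
            ]

    # ------------------------------------------------------------------ #
    def all_layers(self):
        return self.image_layers + self.sex_layers + self.head_layers

    def parameters(self):
        return parameters(self.all_layers())

    def uses_sex(self) -> bool:
        return self.spec.variant in ("cnn_mlp", "cnn_linear_sex")

    def forward(
        self,
        vols: np.ndarray,
        sex: np.ndarray | None = None,
        *,
        training: bool = False,
        rng=None,
        record: bool = False,
    ) -> np.ndarray:
        """Run a batch; returns standardized-age scalars of shape (N,)."""
        dtype = np.dtype(self.spec.dtype).type
        h = np.asarray(vols, dtype=dtype)
        if h.ndim == 4:
            h = h[:, None]
        if h.shape[2:] != self.spec.input_shape:
            raise ValueError(
                f"volume shape {h.shape[2:]} does not match model input "
                f"shape {self.spec.input_shape}"
            )
        self._image_acts = [] if record else None
        for layer in self.image_layers:
            h = layer.forward(h, training=training, rng=rng)
            if record:
                self._image_acts.append(h)

        if self.uses_sex():
            if sex is None:
                raise ValueError(f"variant {self.spec.variant} requires a sex input")
            s = np.asarray(sex, dtype=dtype)
            for layer in self.sex_layers:
                s = layer.forward(s, training=training, rng=rng)
            self._n_img = h.shape[1]
            z = np.concatenate([h, s], axis=1)
        else:
            z = h
        for layer in self.head_layers:
            z = layer.forward(z, training=training, rng=rng)
        return z[:, 0]

    def backward(self, dout: np.ndarray, *, record: bool = False):
        """Backprop d(loss)/d(output); parameter grads land in the layers.

        With ``record=True`` the gradient arriving at every image-path
        activation is kept in ``self._image_grads`` (for Grad-CAM).
        """
        g = np.asarray(dout, dtype=np.dtype(self.spec.dtype).type)[:, None]
        for layer in reversed(self.head_layers):
            g = layer.backward(g)
        if self.uses_sex():
            g_img, g_sex = g[:, : self._n_img], g[:, self._n_img :]
            for layer in reversed(self.sex_layers):
                g_sex = layer.backward(g_sex)
        else:
            g_img = g
        self._image_grads = [None] * len(self.image_layers) if record else None
        for i in reversed(range(len(self.image_layers))):
            if record:
                self._image_grads[i] = g_img
            g_img = self.image_layers[i].backward(g_img)
        return g_img

    def predict_ages(
        self, vols: np.ndarray, sex: np.ndarray | None = None
    ) -> np.ndarray:
        raw = self.forward(vols, sex, training=False)
        return raw * self.y_std + self.y_mean

    # ------------------------------------------------------------------ #
    def save(self, path: str) -> None:
        """Persist parameters, BN statistics and target scaling as .npz."""
        arrays = {}
        for i, layer in enumerate(self.all_layers()):
            for name, p in layer.params.items():
                arrays[f"p_{i}_{name}"] = p
            if isinstance(layer, BatchNorm):
                arrays[f"rm_{i}"] = layer.running_mean
                arrays[f"rv_{i}"] = layer.running_var
        meta = dict(asdict(self.spec))
        arrays["meta"] = np.frombuffer(
            json.dumps(
                {
                    "spec": meta,
                    "init_seed": self.init_seed,
                    "y_mean": float(self.y_mean),
                    "y_std": float(self.y_std),
                    "fingerprint": self.fingerprint,
                }
            ).encode(),
            dtype=np.uint8,
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str) -> "Predictor":
        with np.load(path) as f:
            meta = json.loads(bytes(f["meta"].tobytes()).decode())
            spec_d = meta["spec"]
            for key in ("input_shape", "dense_image_units", "mlp_sex_units", "head_units"):
                spec_d[key] = tuple(spec_d[key])
            model = cls(ModelSpec(**spec_d), init_seed=meta["init_seed"])
            model.y_mean = meta["y_mean"]
            model.y_std = meta["y_std"]
            model.fingerprint = meta["fingerprint"]
            for i, layer in enumerate(model.all_layers()):
                for name in layer.params:
                    layer.params[name] = f[f"p_{i}_{name}"]
                if isinstance(layer, BatchNorm):
                    layer.running_mean = f[f"rm_{i}"]
                    layer.running_var = f[f"rv_{i}"]
        return model


def build_model(spec: ModelSpec, init_seed: int = 0) -> Predictor:
    """Construct an untrained predictor with seeded initialization."""
    return Predictor(spec, init_seed=init_seed)


def records_to_arrays(
    records: list[SubjectRecord], input_shape: tuple[int, int, int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack cohort volumes, sex one-hots and ages into batch arrays."""
    vols, sexes, ages = [], [], []
    for r in records:
        if r.volume is None:
            raise ValueError(f"record {r.subject_id} has no volume attached")
        if r.volume.shape != tuple(input_shape):
            raise ValueError(
                f"record {r.subject_id}: volume shape {r.volume.shape} does not "
                f"match model input shape {tuple(input_shape)}"
            )
        vols.append(r.volume.data)
        sexes.append(sex_onehot(r.sex))
        ages.append(r.age)
    return np.stack(vols), np.stack(sexes), np.asarray(ages, dtype=float)


def predict(model: Predictor, records: list[SubjectRecord], batch_size: int = 16) -> np.ndarray:
    """Predicted ages (years), one finite scalar per record, input order."""
    vols, sexes, _ = records_to_arrays(records, model.spec.input_shape)
    out = []
    for i in range(0, len(records), batch_size):
        out.append(
            model.predict_ages(
                vols[i : i + batch_size],
                sexes[i : i + batch_size] if model.uses_sex() else None,
            )
        )
    pred = np.concatenate(out)
    if not np.all(np.isfinite(pred)):
        raise FloatingPointError("model produced non-finite predictions")
    return pred
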