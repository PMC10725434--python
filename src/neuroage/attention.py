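"""Grad-CAM for scalar regression: per-subject, average and difference maps.

Channel weights are the spatial mean of the gradient of the scalar
output with respect to a conv block's post-ReLU activations; the map is
ReLU(sum_c weight_c * activation_c), trilinearly upsampled to the input
grid and (by default) min-max normalized per subject into [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .model import Predictor, records_to_arrays
from .types import SubjectRecord


@dataclass
class AttentionMap:
    data: np.ndarray
    normalized: bool

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("attention map must be 3D")
        if self.normalized and (self.data.min() < 0 or self.data.max() > 1):
            raise ValueError("normalized map must lie in [0,1]")


def _minmax(raw: np.ndarray) -> np.ndarray:
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.zeros_like(raw)
    return (raw - lo) / (hi - lo)


def _upsample_trilinear(small: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    if small.shape == tuple(shape):
        return small
    axes = []
    for n_in, n_out in zip(small.shape, shape):
        if n_out == 1 or n_in == 1:
            axes.append(np.zeros(n_out))
        else:
            axes.append(np.linspace(0.0, n_in - 1, n_out))
    coords = np.meshgrid(*axes, indexing="ij")
    return ndimage.map_coordinates(small, np.stack(coords), order=1, mode="nearest")


def gradcam(
    model: Predictor,
    record: SubjectRecord,
    layer: int = -1,
    normalized: bool = True,
) -> AttentionMap:
    """Regression Grad-CAM map for one subject on the model input grid."""
    n_blocks = len(model.block_relu_idx)
    if not -n_blocks <= layer < n_blocks:
        raise IndexError(f"conv block index {layer} out of range for {n_blocks} blocks")
    target = model.block_relu_idx[layer]

    vols, sexes, _ = records_to_arrays([record], model.spec.input_shape)
    model.forward(vols, sexes if model.uses_sex() else None, training=False, record=True)
    acts = model._image_acts[target][0]  # (C, d, h, w)
    model.backward(np.ones(1), record=True)
    grads = model._image_grads[target][0]  # d(output)/d(activation)

    weights = grads.mean(axis=(1, 2, 3))  # (C,)
    raw = np.maximum((weights[:, None, None, None] * acts).sum(axis=0), 0.0)
    raw = _upsample_trilinear(np.asarray(raw, dtype=float), model.spec.input_shape)
    if normalized:
        return AttentionMap(data=_minmax(raw), normalized=True)
    return AttentionMap(data=raw, normalized=False)


def average_attention(maps: list[AttentionMap]) -> AttentionMap:
    """Voxel-wise arithmetic mean of same-shape maps."""
    if not maps:
        raise ValueError("cannot average an empty list of maps")
    shapes = {m.data.shape for m in maps}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent map shapes: {shapes}")
    mean = np.mean([m.data for m in maps], axis=0)
    return AttentionMap(data=mean, normalized=all(m.normalized for m in maps))


def difference_attention(
    male_maps: list[AttentionMap],
    female_maps: list[AttentionMap],
    normalized: bool = True,
) -> AttentionMap:
    """mean(male) - mean(female), min-max normalized to [0,1] by default."""
    if not male_maps or not female_maps:
        raise ValueError("both groups must be nonempty")
    diff = average_attention(male_maps).data - average_attention(female_maps).data
    if normalized:
        return AttentionMap(data=_minmax(diff), normalized=True)
    return AttentionMap(data=diff, normalized=False)


def cohort_attention(
    model: Predictor, records: list[SubjectRecord], layer: int = -1
) -> dict[str, AttentionMap]:
    """Global average map plus the male-minus-female difference map."""
    maps = {r.subject_id: gradcam(model, r, layer=layer) for r in records}
    by_sex = {"male": [], "female": []}
    for r in records:
        by_sex[r.sex].append(maps[r.subject_id])
    out = {"average": average_attention(list(maps.values()))}
    if by_sex["male"] and by_sex["female"]:
        out["sex_difference"] = difference_attention(by_sex["male"], by_sex["female"])
    return out
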