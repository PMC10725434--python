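"""Core value types shared across the package."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

SEXES = ("male", "female")


@dataclass
class VolumeImage:
    """A 3D intensity grid with voxel spacing (mm) and world origin (mm).

    The array is always 3D and finite; spacing is strictly positive on
    every axis. This is the imaging unit consumed by every other module.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.5, 1.5, 1.5)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"VolumeImage requires a 3D array, got {self.data.ndim}D "
                f"with shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("VolumeImage data must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical size of the grid along each axis."""
        return tuple(n * s for n, s in zip(self.data.shape, self.spacing))

    def copy(self) -> "VolumeImage":
        return replace(self, data=self.data.copy())


@dataclass
class SubjectRecord:
    """One subject: id, chronological age (years), sex, and the volume."""

    subject_id: str
    age: float
    sex: str
    volume: Optional[VolumeImage] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        self.age = float(self.age)

    def with_volume(self, volume: VolumeImage) -> "SubjectRecord":
        return replace(self, volume=volume)


def sex_onehot(sex: str) -> np.ndarray:
    """Encode sex as a length-2 one-hot vector (male, female)."""
    if sex not in SEXES:
        raise ValueError(f"sex must be one of {SEXES}, got {sex!r}")
    v = np.zeros(2)
    v[SEXES.index(sex)] = 1.0
    return v
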