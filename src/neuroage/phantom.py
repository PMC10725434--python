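"""Synthetic registered brain phantoms whose morphology encodes age and sex.

A phantom is a bright spherical cortical shell around medium-intensity
parenchyma with a dark central "ventricle". The ventricle radius grows
linearly with age and the shell thins linearly with age, so downstream
age-regression has a known geometric signal, localized at the ventricle.
Sex enters twice: an intensity scaling of a designated anterior subregion
(a visible cue) and, optionally, a sex-specific multiplier on the
ventricle growth rate (an invisible-from-anatomy cue that only a model
receiving the sex label can exploit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .types import SEXES, SubjectRecord, VolumeImage

AGE_RANGE = (18.0, 90.0)

# Intensity levels (arbitrary units). The periventricular rim is the
# brightest structure so the age-varying boundary, not the static outer
# shell, is the most salient edge for attribution.
_BG = 0.0
_VENTRICLE = 0.05
_PARENCHYMA = 0.5
_SHELL = 1.0
_RIM = 1.3


@dataclass
class PhantomParams:
    """Geometry and noise parameters of the phantom generator.

    Radii and thicknesses are in millimetres; slopes are mm per year of
    age. ``sex_scale_male`` multiplies the intensity of the designated
    anterior subregion for male subjects; ``ventricle_male_slope_factor``
    multiplies the ventricle growth slope for males (1.0 disables the
    sex-dependent aging trajectory).
    """

    grid_shape: tuple[int, int, int] = (16, 16, 16)
    spacing: tuple[float, float, float] = (1.5, 1.5, 1.5)
    ventricle_base_radius: float = 1.5
    ventricle_age_slope: float = 0.035
    shell_base_thickness: float = 3.6
    shell_age_slope: float = -0.02
    sex_scale_male: float = 1.1
    ventricle_male_slope_factor: float = 1.0
    male_age_offset: float = 0.0
    rim_thickness: float = 2.0
    brain_radius: float | None = None
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if len(self.grid_shape) != 3 or any(n < 16 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be >= (16,16,16), got {self.grid_shape}")
        lo, hi = AGE_RANGE
        for age in (lo, hi):
            for sex in SEXES:
                if self.ventricle_radius_at(age, sex) <= 0:
                    raise ValueError(f"{sex} ventricle radius non-positive at age {age}")
                if self.shell_thickness_at(age, sex) <= 0:
                    raise ValueError(f"{sex} shell thickness non-positive at age {age}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def effective_age(self, age: float, sex: str) -> float:
        """Morphological age: males are shifted by ``male_age_offset`` years."""
        return age + (self.male_age_offset if sex == "male" else 0.0)

    def ventricle_radius_at(self, age: float, sex: str = "female") -> float:
        """Closed-form ventricle radius (mm) at a given age and sex."""
        slope = self.ventricle_age_slope
        if sex == "male":
            slope *= self.ventricle_male_slope_factor
        return self.ventricle_base_radius + slope * self.effective_age(age, sex)

    def shell_thickness_at(self, age: float, sex: str = "female") -> float:
        """Closed-form cortical shell thickness (mm) at a given age."""
        return self.shell_base_thickness + self.shell_age_slope * self.effective_age(age, sex)

    def brain_radius_mm(self) -> float:
        if self.brain_radius is not None:
            return float(self.brain_radius)
        half_extent = min(n * s for n, s in zip(self.grid_shape, self.spacing)) / 2.0
        return 0.92 * half_extent


@dataclass
class AugmentConfig:
    """Random rigid augmentation: Euler rotation then integer translation."""

    probability: float = 0.3
    rotation_range_deg: float = 10.0
    translation_range_vox: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"probability must be in [0,1], got {self.probability}")
        if self.rotation_range_deg < 0 or self.translation_range_vox < 0:
            raise ValueError("augmentation ranges must be >= 0")


def _grid_radii_mm(params: PhantomParams) -> np.ndarray:
    """Distance of each voxel centre from the grid centre, in mm."""
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * s
        for n, s in zip(params.grid_shape, params.spacing)
    ]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    return np.sqrt(zz**2 + yy**2 + xx**2)


def ventricle_mask(params: PhantomParams, age: float, sex: str = "female") -> np.ndarray:
    """Boolean mask of the dark central ventricle at a given age."""
    r = _grid_radii_mm(params)
    return r < params.ventricle_radius_at(age, sex)


def sex_region_mask(params: PhantomParams) -> np.ndarray:
    """Designated anterior subregion whose intensity is scaled for males.

    A box in the anterior (axis-1 high-index) third of the grid,
    restricted to parenchyma-range radii so it never touches shell or
    ventricle over the supported age range.
    """
    nz, ny, nx = params.grid_shape
    box = np.zeros(params.grid_shape, dtype=bool)
    box[nz // 3 : 2 * nz // 3, 2 * ny // 3 :, nx // 3 : 2 * nx // 3] = True
    r = _grid_radii_mm(params)
    r_vent_max = max(
        params.ventricle_radius_at(a, s) for a in AGE_RANGE for s in SEXES
    )
    t_max = max(params.shell_thickness_at(a, s) for a in AGE_RANGE for s in SEXES)
    inner = params.brain_radius_mm() - t_max
    return box & (r > r_vent_max + params.rim_thickness) & (r < inner)


def generate_phantom(
    age: float, sex: str, params: PhantomParams, subject_seed: int
) -> VolumeImage:
    """Deterministically synthesize one registered phantom volume."""
    lo, hi = AGE_RANGE
    if not lo <= age <= hi:
        raise ValueError(f"age {age} outside supported range [{lo}, {hi}]")
    if sex not in SEXES:
        raise ValueError(f"sex must be one of {SEXES}, got {sex!r}")

    r = _grid_radii_mm(params)
    r_brain = params.brain_radius_mm()
    thickness = params.shell_thickness_at(age, sex)
    r_vent = params.ventricle_radius_at(age, sex)
    if r_vent <= 0 or thickness <= 0:
        raise ValueError("derived radius/thickness non-positive at this age")

    vol = np.full(params.grid_shape, _BG)
    vol[r < r_brain] = _SHELL
    vol[r < r_brain - thickness] = _PARENCHYMA
    if params.rim_thickness > 0:
        # bright periventricular rim that tracks the ventricle boundary
        rim_outer = min(r_vent + params.rim_thickness, r_brain - thickness)
        vol[(r >= r_vent) & (r < rim_outer)] = _RIM
    vol[r < r_vent] = _VENTRICLE

    if params.sex_scale_male != 1.0 and sex == "male":
        region = sex_region_mask(params)
        vol[region] *= params.sex_scale_male

    if params.noise_sd > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=params.seed, spawn_key=(int(subject_seed),))
        )
        vol = vol + rng.normal(0.0, params.noise_sd, size=vol.shape)

    return VolumeImage(data=vol, spacing=params.spacing)


def generate_cohort(
    n: int,
    age_low: float = AGE_RANGE[0],
    age_high: float = AGE_RANGE[1],
    male_fraction: float = 0.5,
    params: PhantomParams | None = None,
    seed: int = 0,
) -> list[SubjectRecord]:
    """Draw a cohort of phantoms with uniform ages and Bernoulli sexes."""
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    if params is None:
        params = PhantomParams()
    if not (AGE_RANGE[0] <= age_low <= age_high <= AGE_RANGE[1]):
        raise ValueError(
            f"age range [{age_low}, {age_high}] must lie within {AGE_RANGE}"
        )
    rng = np.random.default_rng(seed)
    ages = rng.uniform(age_low, age_high, size=n)
    males = rng.random(n) < male_fraction
    records = []
    for i in range(n):
        sex = "male" if males[i] else "female"
        vol = generate_phantom(ages[i], sex, params, subject_seed=i)
        records.append(
            SubjectRecord(subject_id=f"sub-{i:04d}", age=ages[i], sex=sex, volume=vol)
        )
    return records


def cohort_table(records: list[SubjectRecord]):
    """Demographic table (id, age, sex) for a cohort."""
    import pandas as pd

    return pd.DataFrame(
        {
            "id": [r.subject_id for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
        }
    )


def augment(vol: VolumeImage, cfg: AugmentConfig, draw_seed: int) -> VolumeImage:
    """With probability ``cfg.probability`` apply a random rigid transform.

    Rotation first (three Euler angles, each uniform in the symmetric
    range, about the volume centre, linear interpolation, zero fill),
    then an integer-voxel translation per axis. The grid shape never
    changes and the input is returned untouched on the no-augment draw.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(int(draw_seed),))
    )
    if rng.random() >= cfg.probability:
        return vol

    angles = rng.uniform(-cfg.rotation_range_deg, cfg.rotation_range_deg, size=3)
    shifts = rng.integers(
        -int(cfg.translation_range_vox), int(cfg.translation_range_vox) + 1, size=3
    )

    data = vol.data
    if np.any(angles != 0.0):
        rot = Rotation.from_euler("zyx", angles, degrees=True).as_matrix()
        center = (np.asarray(data.shape) - 1) / 2.0
        # affine_transform maps output coords through the matrix: pull-back
        offset = center - rot.T @ center
        data = ndimage.affine_transform(
            data, rot.T, offset=offset, order=1, mode="constant", cval=0.0
        )
    if np.any(shifts != 0):
        data = ndimage.shift(
            data, shifts, order=0, mode="constant", cval=0.0, prefilter=False
        )
    return VolumeImage(data=data, spacing=vol.spacing, origin=vol.origin)
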