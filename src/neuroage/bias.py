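"""Linear bias correction of the brain-age gap.

The gap (predicted minus chronological age) is regressed on
chronological age by ordinary least squares; the fitted offset
``intercept + slope * age`` is then subtracted from predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class BiasModel:
    intercept: float
    slope: float
    fit_n: int

    def __post_init__(self) -> None:
        if self.fit_n < 2:
            raise ValueError("bias model requires fit_n >= 2")
        if not (np.isfinite(self.intercept) and np.isfinite(self.slope)):
            raise ValueError("bias coefficients must be finite")

    def offset(self, ages) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(ages, dtype=float)


def fit_bias(ages, predicted) -> BiasModel:
    """OLS fit of gap = predicted - age against age."""
    ages = np.asarray(ages, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if ages.shape != predicted.shape or ages.ndim != 1 or ages.size < 2:
        raise ValueError("ages and predicted must be equal-length vectors (n >= 2)")
    if np.var(ages) == 0:
        raise ValueError("zero age variance; bias slope is unidentifiable")
    gap = predicted - ages
    slope, intercept = np.polyfit(ages, gap, deg=1)
    return BiasModel(intercept=float(intercept), slope=float(slope), fit_n=len(ages))


def apply_bias(model: BiasModel, ages, predicted) -> np.ndarray:
    """corrected_i = predicted_i - (intercept + slope * age_i)."""
    predicted = np.asarray(predicted, dtype=float)
    return predicted - model.offset(ages)
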