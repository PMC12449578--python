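"""Phantom-rod density calibration.

Maps raw scanner units to mgCaHA/cc through an ordinary least squares fit
of reference rod densities on measured rod means (forward regression: the
reference densities are exact, the ROI means are noisy, and the fitted
affine map is what is applied per voxel).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import CalibrationError
from .volume import VoxelVolume

__all__ = ["CalibrationModel", "fit_calibration", "apply_calibration"]


@dataclass
class CalibrationModel:
    slope: float  # (mgCaHA/cc) per raw unit
    intercept: float  # mgCaHA/cc
    rod_reference_densities: list[float]
    rod_measured_means: list[float]
    residuals: list[float] = field(default_factory=list)
    r_squared: float = float("nan")

    def __call__(self, raw):
        return self.slope * np.asarray(raw) + self.intercept

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "slope": self.slope,
                    "intercept": self.intercept,
                    "rod_reference_densities": list(self.rod_reference_densities),
                    "rod_measured_means": list(self.rod_measured_means),
                    "residuals": list(self.residuals),
                    "r_squared": self.r_squared,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "CalibrationModel":
        with open(path) as fh:
            return cls(**json.load(fh))


def fit_calibration(measured, reference) -> CalibrationModel:
    """OLS of reference densities on measured raw-unit rod means."""
    x = np.asarray(measured, dtype=float)
    y = np.asarray(reference, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise CalibrationError("measured and reference must be equal-length 1D lists")
    if x.size < 2 or np.unique(y).size < 2:
        raise CalibrationError("need at least two rods with distinct reference densities")
    if np.ptp(x) == 0:
        raise CalibrationError("all measured rod values identical; singular fit")
    A = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    slope, intercept = (float(c) for c in coef)
    pred = slope * x + intercept
    resid = y - pred
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else float("nan")
    if not np.isfinite(slope) or slope == 0:
        raise CalibrationError("degenerate calibration slope")
    return CalibrationModel(
        slope=slope,
        intercept=intercept,
        rod_reference_densities=y.tolist(),
        rod_measured_means=x.tolist(),
        residuals=resid.tolist(),
        r_squared=r2,
    )


def apply_calibration(volume: VoxelVolume, model: CalibrationModel) -> VoxelVolume:
    """Affine per-voxel transform to calibrated density units.

    Guards against double calibration: the input must be flagged raw.
    """
    if volume.calibrated:
        raise CalibrationError("volume is already calibrated")
    out = volume.copy(values=model(volume.values))
    out.calibrated = True
    out.meta["calibration"] = {"slope": model.slope, "intercept": model.intercept}
    return out
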