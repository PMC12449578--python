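"""Calibrated voxel volumes — the pipeline currency.

A :class:`VoxelVolume` holds a rectangular 3D grid of bone mineral density
values in mgCaHA/cc (or raw scanner units before calibration) together with
its voxel spacing and origin.  The axis order convention is
``(x in-plane, y in-plane, z cranio-caudal)``; world coordinates refer to
voxel centers, ``world = origin + index * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .errors import CorticonError

__all__ = ["VoxelVolume"]


@dataclass
class VoxelVolume:
    """A 3D density image with spacing/origin metadata.

    Parameters
    ----------
    values
        3D array, shape ``(nx, ny, nz)``.
    spacing
        Voxel spacing in mm per axis, strictly positive.
    origin
        World coordinate of the center of voxel (0, 0, 0), mm.
    calibrated
        Whether values are in mgCaHA/cc (``True``) or raw scanner units.
    meta
        Free-form provenance dictionary (generator truth, calibration, ...).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    calibrated: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise CorticonError("VoxelVolume requires a 3D value grid")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise CorticonError("spacing must be three strictly positive lengths")
        if not np.all(np.isfinite(self.values)):
            raise CorticonError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def axis_coordinates(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis (mm)."""
        n = self.values.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def total_mass_mg(self) -> float:
        """Total mineral mass, sum of density x voxel volume (mg).

        Density is mg/cc = mg / 1000 mm^3.
        """
        return float(self.values.sum(dtype=np.float64)) * self.voxel_volume_mm3 / 1000.0

    def copy(self, values: np.ndarray | None = None) -> "VoxelVolume":
        return VoxelVolume(
            values=self.values.copy() if values is None else values,
            spacing=self.spacing,
            origin=self.origin,
            calibrated=self.calibrated,
            meta=dict(self.meta),
        )

    # -- NIfTI I/O ---------------------------------------------------------

    def to_nifti(self, path) -> None:
        affine = np.diag(list(self.spacing) + [1.0])
        affine[:3, 3] = self.origin
        img = nib.Nifti1Image(np.asarray(self.values, dtype=np.float32), affine)
        img.header.set_zooms(self.spacing)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path, calibrated: bool = True) -> "VoxelVolume":
        img = nib.load(str(path))
        affine = img.affine
        spacing = tuple(float(abs(affine[i, i])) for i in range(3))
        origin = tuple(float(affine[i, 3]) for i in range(3))
        return cls(
            values=np.asarray(img.get_fdata(), dtype=np.float32),
            spacing=spacing,
            origin=origin,
            calibrated=calibrated,
        )
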