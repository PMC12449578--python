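"""Threshold-based cancellous metrics: BV/TV, TMD, compartment BMD/BMC.

BV/TV is the percentage of trabecular-VOI voxels strictly above the
mineral threshold (default 250 mg/cc); TMD is the mean density of those
supra-threshold voxels and is undefined when none exceed the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CorticonError
from .segmentation import CortexSegmentation, VoiLabel
from .volume import VoxelVolume

__all__ = ["CancellousResult", "bvtv", "tmd", "compartment_bmd_bmc"]

DEFAULT_THRESHOLD = 250.0


@dataclass
class CancellousResult:
    compartment: str
    bvtv: float = float("nan")  # percent
    tmd: float = float("nan")  # mg/cc; NaN when undefined
    tmd_defined: bool = True
    compartment_bmd: float = float("nan")  # mg/cc
    compartment_bmc: float = float("nan")  # mg
    threshold: float = DEFAULT_THRESHOLD


def _masked(volume: VoxelVolume, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if not volume.calibrated:
        raise CorticonError("volume must be calibrated")
    if mask.shape != volume.shape:
        raise CorticonError("mask shape mismatch")
    if not mask.any():
        raise CorticonError("empty trabecular mask")
    return np.asarray(volume.values)[mask]


def bvtv(volume: VoxelVolume, mask: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> float:
    """Bone volume fraction: % of mask voxels strictly above threshold."""
    vals = _masked(volume, mask)
    return 100.0 * float(np.count_nonzero(vals > threshold)) / vals.size


def tmd(volume: VoxelVolume, mask: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> float:
    """Mean density of supra-threshold voxels; NaN when none qualify."""
    vals = _masked(volume, mask)
    above = vals[vals > threshold]
    if above.size == 0:
        return float("nan")
    return float(above.mean())


def compartment_bmd_bmc(
    volume: VoxelVolume,
    seg: CortexSegmentation,
    compartment: VoiLabel | str,
    threshold: float = DEFAULT_THRESHOLD,
) -> CancellousResult:
    """Full cancellous summary for one segmentation compartment."""
    label = VoiLabel[compartment] if isinstance(compartment, str) else compartment
    mask = seg.voi_mask(label)
    if not mask.any():
        raise CorticonError(f"compartment {label.name} is empty")
    vals = _masked(volume, mask)
    t = tmd(volume, mask, threshold)
    return CancellousResult(
        compartment=label.name,
        bvtv=bvtv(volume, mask, threshold),
        tmd=t,
        tmd_defined=bool(np.isfinite(t)),
        compartment_bmd=float(vals.mean()),
        compartment_bmc=float(vals.sum(dtype=np.float64)) * volume.voxel_volume_mm3 / 1000.0,
        threshold=threshold,
    )
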