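"""Digital vertebral phantoms and HR-QCT acquisition simulation.

The phantom forge renders ground-truth vertebral bodies — an elliptic
cylinder with a thin (~200-600 um) cortical shell of fixed tissue mineral
density over a trabecular interior — and simulates their acquisition on a
clinical CT scanner: Gaussian point-spread-function blur, box averaging
over the slice thickness, resampling to the HR-QCT voxel grid, and
additive white noise in calibrated units.  Longitudinal pairs add slabs of
partially mineralized matrix at the endosteal and/or periosteal surface so
that every downstream estimator can be validated against known truth.

Geometry convention: the periosteal boundary is an ellipse with the given
outer semi-axes; the endosteal boundary is its inward normal offset by the
cortical width, so the shell has constant thickness along the local
normal.  Signed in-plane distance to the periosteal surface is positive
outward.  Sub-voxel partial volume is handled by linear area-fraction
ramps on the supersampled render grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.special import ellipe

from .errors import CorticonError, ResolutionError
from .volume import VoxelVolume

__all__ = [
    "PhantomSpec",
    "TrabecularNetwork",
    "ImagingSpec",
    "AppositionTruth",
    "ArmSpec",
    "SubjectTruth",
    "SCANNER_PRESETS",
    "render_phantom",
    "acquire",
    "make_longitudinal_pair",
    "generate_cohort",
    "realize_subject",
    "save_truth_record",
    "load_truth_record",
]


# Scanner presets: reconstruction-kernel-specific Gaussian PSF sigma (mm)
# and slice thickness (mm) for the three scanner models of the emulated
# study (Siemens Somatom AS / B70s, Philips Brilliance 64 / D,
# GE Lightspeed 16 / BONE).
SCANNER_PRESETS = {
    "SIEMENS_B70S": {"psf_sigma": 0.39, "slice_thickness": 1.00},
    "PHILIPS_D": {"psf_sigma": 0.61, "slice_thickness": 1.00},
    "GE_BONE": {"psf_sigma": 0.55, "slice_thickness": 1.25},
}


@dataclass
class TrabecularNetwork:
    """Optional rod-lattice trabecular interior (for BV/TV truth tests).

    Struts of density ``strut_density`` run along all three axes on a cubic
    lattice; the lattice-distance field is thresholded so that exactly
    ``round(bvtv_true * n_core_voxels)`` interior voxels are bone.
    """

    bvtv_true: float
    strut_spacing: float = 1.2  # mm
    strut_density: float = 900.0  # mgCaHA/cc

    def __post_init__(self):
        if not 0.0 <= self.bvtv_true <= 1.0:
            raise CorticonError("bvtv_true must be in [0, 1]")
        if self.strut_spacing <= 0:
            raise CorticonError("strut_spacing must be positive")


@dataclass
class PhantomSpec:
    """Ground-truth geometry and composition of one vertebral phantom.

    Lengths in mm except ``cortical_width_true`` (um); densities in
    mgCaHA/cc.  The default geometry is a scaled-down vertebral body whose
    cortical width matches the study-scale baseline (~359 um).
    """

    outer_semi_axes: tuple[float, float] = (9.0, 7.0)
    body_height: float = 12.0
    cortical_width_true: float = 359.0  # um
    cortical_tmd: float = 1100.0
    trabecular_bmd: float = 115.0
    trabecular_network: TrabecularNetwork | None = None
    background_bmd: float = 0.0
    endplate_width: float = 0.8
    seed: int = 0

    def __post_init__(self):
        a, b = self.outer_semi_axes
        if a <= 0 or b <= 0 or self.body_height <= 0:
            raise CorticonError("phantom geometry must have positive extents")
        if self.cortical_width_true <= 0:
            raise CorticonError("cortical_width_true must be > 0")
        plateau = (
            self.trabecular_network.strut_density
            if self.trabecular_network is not None
            else self.trabecular_bmd
        )
        if self.cortical_tmd < plateau:
            raise CorticonError("cortical_tmd must be >= trabecular density")
        if self.endplate_width < 0 or 2 * self.endplate_width >= self.body_height:
            raise CorticonError("endplate_width invalid for body height")

    @property
    def cortical_width_mm(self) -> float:
        return self.cortical_width_true / 1000.0


@dataclass
class ImagingSpec:
    """HR-QCT acquisition parameters.

    ``psf_sigma_inplane``/``psf_sigma_z`` are the Gaussian PSF widths (mm);
    slice profile is modeled as a box average over ``slice_thickness``
    applied after the Gaussian blur.  ``noise_sd`` is white Gaussian noise
    in calibrated density units.
    """

    psf_sigma_inplane: float = 0.55
    psf_sigma_z: float = 0.55
    voxel_spacing: tuple[float, float, float] = (0.2, 0.2, 0.3)
    slice_thickness: float = 1.25
    noise_sd: float = 25.0
    scanner_preset: str = "CUSTOM"

    def __post_init__(self):
        if self.psf_sigma_inplane < 0 or self.psf_sigma_z < 0:
            raise CorticonError("PSF sigma must be >= 0")
        if any(s <= 0 for s in self.voxel_spacing) or self.slice_thickness <= 0:
            raise CorticonError("voxel spacing and slice thickness must be > 0")
        if self.noise_sd < 0:
            raise CorticonError("noise_sd must be >= 0")

    @classmethod
    def preset(cls, name: str, **overrides) -> "ImagingSpec":
        if name not in SCANNER_PRESETS:
            raise CorticonError(f"unknown scanner preset {name!r}")
        p = SCANNER_PRESETS[name]
        kwargs = dict(
            psf_sigma_inplane=p["psf_sigma"],
            psf_sigma_z=p["psf_sigma"],
            slice_thickness=p["slice_thickness"],
            scanner_preset=name,
        )
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class AppositionTruth:
    """Ground-truth longitudinal change at the cortical surfaces.

    ``endosteal_matrix``/``periosteal_matrix`` are new-matrix slab widths in
    um; the slabs carry density ``mineralization_fraction x cortical TMD``
    on top of the tissue they are deposited into.
    """

    endosteal_matrix: float = 0.0  # um
    periosteal_matrix: float = 0.0  # um
    mineralization_fraction: float = 0.5
    existing_cortex_tmd_change: float = 0.0  # mgCaHA/cc

    def __post_init__(self):
        if self.endosteal_matrix < 0 or self.periosteal_matrix < 0:
            raise CorticonError("apposition widths must be >= 0")
        if not 0.0 < self.mineralization_fraction <= 1.0:
            raise CorticonError("mineralization_fraction must be in (0, 1]")


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------


def ellipse_signed_distance(x, y, a, b, n_boundary: int = 8192):
    """Signed Euclidean distance from points to the ellipse x^2/a^2+y^2/b^2=1.

    Negative inside, positive outside.  Computed against a dense boundary
    polyline (chord error ~ (arc/8192)^2 / curvature radius, sub-micron for
    centimeter-scale ellipses).
    """
    t = np.linspace(0.0, 2.0 * np.pi, n_boundary, endpoint=False)
    boundary = np.column_stack([a * np.cos(t), b * np.sin(t)])
    pts = np.column_stack([np.ravel(x), np.ravel(y)])
    d, _ = cKDTree(boundary).query(pts, workers=-1)
    inside = (np.ravel(x) / a) ** 2 + (np.ravel(y) / b) ** 2 < 1.0
    return np.where(inside, -d, d).reshape(np.shape(x))


def ellipse_offset_area(a: float, b: float, t: float) -> float:
    """Area enclosed by the outward normal offset (distance t) of an ellipse.

    A(t) = pi*a*b + P*t + pi*t^2 for a convex curve with perimeter P;
    negative t gives the inward offset (valid while it stays regular).
    """
    m = 1.0 - (min(a, b) / max(a, b)) ** 2
    perimeter = 4.0 * max(a, b) * ellipe(m)
    return np.pi * a * b + perimeter * t + np.pi * t * t


def _coverage_inside(d: np.ndarray, boundary: float, h: float) -> np.ndarray:
    """Linear-ramp coverage fraction of the region {distance < boundary}.

    ``d`` is the signed distance field and ``h`` the pixel size; a pixel
    whose center sits exactly on the boundary is half covered.
    """
    return np.clip(0.5 - (d - boundary) / h, 0.0, 1.0)


def _interval_overlap(lo: np.ndarray, hi: np.ndarray, a: float, b: float) -> np.ndarray:
    """Fraction of each [lo, hi) cell covered by [a, b]."""
    return np.clip(
        (np.minimum(hi, b) - np.maximum(lo, a)) / (hi - lo), 0.0, 1.0
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _grid(spec: PhantomSpec, supersampling: int, voxel_spacing, margin: float):
    """Target and fine grid layout centered on the phantom."""
    a, b = spec.outer_semi_axes
    extents = (2 * a + 2 * margin, 2 * b + 2 * margin, spec.body_height + 2 * margin)
    target_shape = tuple(
        int(np.ceil(e / s)) for e, s in zip(extents, voxel_spacing)
    )
    fine_shape = tuple(n * supersampling for n in target_shape)
    fine_spacing = tuple(s / supersampling for s in voxel_spacing)
    center = tuple(n * s / 2.0 for n, s in zip(target_shape, voxel_spacing))
    return target_shape, fine_shape, fine_spacing, center


def _render_fields(spec: PhantomSpec, supersampling: int, voxel_spacing, margin: float):
    """Shared geometry fields for baseline and follow-up truth rendering."""
    target_shape, fine_shape, fine_spacing, center = _grid(
        spec, supersampling, voxel_spacing, margin
    )
    w = spec.cortical_width_mm
    if w < min(fine_spacing[:2]):
        raise ResolutionError(
            f"cortical width {w:.3f} mm below supersampled pixel "
            f"{min(fine_spacing[:2]):.3f} mm; increase supersampling"
        )
    fx = (np.arange(fine_shape[0]) + 0.5) * fine_spacing[0] - center[0]
    fy = (np.arange(fine_shape[1]) + 0.5) * fine_spacing[1] - center[1]
    fz = (np.arange(fine_shape[2]) + 0.5) * fine_spacing[2] - center[2]
    X, Y = np.meshgrid(fx, fy, indexing="ij")
    a, b = spec.outer_semi_axes
    d = ellipse_signed_distance(X, Y, a, b).astype(np.float64)

    h = max(fine_spacing[:2])
    cov_peri = _coverage_inside(d, 0.0, h)
    cov_endo = _coverage_inside(d, -w, h)

    # z band coverages (fractions of each fine voxel's z-extent)
    z0, z1 = -spec.body_height / 2.0, spec.body_height / 2.0
    lo = fz - fine_spacing[2] / 2.0
    hi = fz + fine_spacing[2] / 2.0
    w_body = _interval_overlap(lo, hi, z0, z1)
    ep = spec.endplate_width
    w_ep = _interval_overlap(lo, hi, z0, z0 + ep) + _interval_overlap(lo, hi, z1 - ep, z1)
    w_vert = np.clip(w_body - w_ep, 0.0, 1.0)

    return {
        "target_shape": target_shape,
        "fine_shape": fine_shape,
        "fine_spacing": fine_spacing,
        "center": center,
        "d": d,
        "h": h,
        "cov_peri": cov_peri,
        "cov_endo": cov_endo,
        "w_vert": w_vert,
        "w_ep": w_ep,
        "width_mm": w,
    }


def _compose_truth(spec: PhantomSpec, F: dict) -> tuple[np.ndarray, dict]:
    """Assemble the piecewise-constant truth volume from coverage fields."""
    bg = spec.background_bmd
    T = spec.cortical_tmd
    cort = F["cov_peri"] - F["cov_endo"]  # cortical shell fraction, in-plane
    meta: dict = {}

    if spec.trabecular_network is None:
        interior_plane = spec.trabecular_bmd * F["cov_endo"]
    else:
        interior_plane = None  # handled in 3D below

    vals = np.empty(F["fine_shape"], dtype=np.float32)
    wv = F["w_vert"]
    we = F["w_ep"]
    if interior_plane is not None:
        plane_vert = (T - bg) * cort + (spec.trabecular_bmd - bg) * F["cov_endo"]
        plane_ep = (T - bg) * F["cov_peri"]
        vals[:] = (
            bg
            + plane_vert[:, :, None] * wv[None, None, :]
            + plane_ep[:, :, None] * we[None, None, :]
        )
    else:
        net = spec.trabecular_network
        plane_vert = (T - bg) * cort
        plane_ep = (T - bg) * F["cov_peri"]
        vals[:] = (
            bg
            + plane_vert[:, :, None] * wv[None, None, :]
            + plane_ep[:, :, None] * we[None, None, :]
        )
        # strictly-interior core voxels in fully vertical fine slices
        core_plane = F["cov_endo"] >= 1.0
        core = core_plane[:, :, None] & (wv[None, None, :] >= 1.0)
        n_core = int(core.sum())
        if n_core == 0:
            raise CorticonError("no interior voxels available for the network")
        sp = net.strut_spacing
        fxm = np.abs(((np.arange(F["fine_shape"][0]) + 0.5) * F["fine_spacing"][0]) % sp - sp / 2)
        fym = np.abs(((np.arange(F["fine_shape"][1]) + 0.5) * F["fine_spacing"][1]) % sp - sp / 2)
        fzm = np.abs(((np.arange(F["fine_shape"][2]) + 0.5) * F["fine_spacing"][2]) % sp - sp / 2)
        rod_z = np.hypot(fxm[:, None], fym[None, :])[:, :, None]
        rod_x = np.hypot(fym[:, None], fzm[None, :])[None, :, :]
        rod_y = np.hypot(fxm[:, None], fzm[None, :])[:, None, :]
        lattice = np.minimum(np.broadcast_to(rod_z, F["fine_shape"]),
                             np.minimum(np.broadcast_to(rod_x, F["fine_shape"]),
                                        np.broadcast_to(rod_y, F["fine_shape"])))
        k = int(round(net.bvtv_true * n_core))
        core_idx = np.flatnonzero(core)
        order = np.argsort(lattice.ravel()[core_idx], kind="stable")
        bone_idx = core_idx[order[:k]]
        flat = vals.reshape(-1)
        flat[bone_idx] = net.strut_density
        meta["network_core_voxels"] = n_core
        meta["network_bone_voxels"] = k
        meta["achieved_bvtv"] = k / n_core
        meta["network_core_mask_fine"] = core
    return vals, meta


def render_phantom(
    spec: PhantomSpec,
    supersampling: int = 4,
    voxel_spacing: tuple[float, float, float] = (0.2, 0.2, 0.3),
    margin: float = 3.0,
) -> VoxelVolume:
    """Render the un-blurred ground-truth volume on a supersampled grid.

    The returned grid is ``supersampling`` x finer than the target voxel
    grid along every axis, so :func:`acquire` can resample back by exact
    block averaging.  Partial volume at the analytic boundaries is handled
    by linear area-fraction ramps.
    """
    if supersampling < 1:
        raise CorticonError("supersampling must be >= 1")
    F = _render_fields(spec, supersampling, voxel_spacing, margin)
    vals, meta = _compose_truth(spec, F)
    vol = VoxelVolume(
        values=vals,
        spacing=F["fine_spacing"],
        origin=tuple(s / 2.0 for s in F["fine_spacing"]),
        calibrated=True,
        meta={
            "kind": "truth",
            "target_spacing": tuple(voxel_spacing),
            "supersampling": supersampling,
            "phantom_center": F["center"],
            **meta,
        },
    )
    return vol


def acquire(truth: VoxelVolume, imaging: ImagingSpec, seed: int = 0) -> VoxelVolume:
    """Simulate HR-QCT acquisition of a ground-truth volume.

    Gaussian PSF blur -> box average over the slice thickness along z ->
    block-average resample to the target voxel grid -> additive white
    Gaussian noise.  Blur and resampling conserve total mineral mass (the
    identity every deconvolution step downstream relies on).
    """
    fs = truth.spacing
    ts = imaging.voxel_spacing
    ratios = [t / f for t, f in zip(ts, fs)]
    int_ratios = [int(round(r)) for r in ratios]
    if any(ir < 1 or abs(r - ir) > 1e-6 for r, ir in zip(ratios, int_ratios)):
        raise CorticonError(
            "truth grid must be an integer refinement of the target grid"
        )
    if any(n % ir for n, ir in zip(truth.shape, int_ratios)):
        raise CorticonError("truth shape not divisible by resampling ratio")

    sig_vox = (
        imaging.psf_sigma_inplane / fs[0],
        imaging.psf_sigma_inplane / fs[1],
        imaging.psf_sigma_z / fs[2],
    )
    vals = np.asarray(truth.values, dtype=np.float32)
    if any(s > 0 for s in sig_vox):
        vals = ndimage.gaussian_filter(vals, sigma=sig_vox, mode="nearest")
    n_slice = max(1, int(round(imaging.slice_thickness / fs[2])))
    if n_slice > 1:
        vals = ndimage.uniform_filter1d(vals, size=n_slice, axis=2, mode="nearest")
    rx, ry, rz = int_ratios
    nx, ny, nz = (n // r for n, r in zip(vals.shape, int_ratios))
    vals = vals.reshape(nx, rx, ny, ry, nz, rz).mean(axis=(1, 3, 5), dtype=np.float64)
    if imaging.noise_sd > 0:
        rng = np.random.default_rng(seed)
        vals = vals + rng.normal(0.0, imaging.noise_sd, size=vals.shape)
    meta = {k: v for k, v in truth.meta.items() if not k.endswith("_fine")}
    meta.update(kind="acquired", scanner_preset=imaging.scanner_preset,
                psf_sigma_inplane=imaging.psf_sigma_inplane,
                psf_sigma_z=imaging.psf_sigma_z,
                slice_thickness=imaging.slice_thickness,
                noise_sd=imaging.noise_sd, noise_seed=int(seed))
    return VoxelVolume(
        values=vals.astype(np.float32),
        spacing=ts,
        origin=tuple(s / 2.0 for s in ts),
        calibrated=True,
        meta=meta,
    )


def make_longitudinal_pair(
    spec: PhantomSpec,
    apposition: AppositionTruth,
    imaging: ImagingSpec,
    seed: int = 0,
    supersampling: int = 4,
    voxel_spacing: tuple[float, float, float] | None = None,
    margin: float = 3.0,
):
    """Image a phantom at baseline and after known surface apposition.

    The follow-up truth adds a slab of density
    ``mineralization_fraction x cortical_tmd`` of the stated matrix width
    inside the endosteal boundary and outside the periosteal boundary
    (vertical wall only), applies any TMD change to the pre-existing shell,
    and both time points are acquired with independent noise draws.

    Returns ``(baseline, followup, truth_record)``.
    """
    vs = imaging.voxel_spacing if voxel_spacing is None else voxel_spacing
    F = _render_fields(spec, supersampling, vs, margin)
    w = F["width_mm"]
    a_e = apposition.endosteal_matrix / 1000.0
    a_p = apposition.periosteal_matrix / 1000.0
    if w + a_e >= min(spec.outer_semi_axes):
        raise CorticonError(
            "endosteal apposition would in-fill the marrow cavity"
        )

    base_vals, meta = _compose_truth(spec, F)
    f = apposition.mineralization_fraction
    slab_density = f * spec.cortical_tmd
    h = F["h"]
    d = F["d"]
    endo_frac = _coverage_inside(d, -w, h) - _coverage_inside(d, -w - a_e, h)
    peri_frac = _coverage_inside(d, a_p, h) - _coverage_inside(d, 0.0, h)
    cort_frac = F["cov_peri"] - F["cov_endo"]

    delta_plane = slab_density * (endo_frac + peri_frac)
    delta_plane = delta_plane + apposition.existing_cortex_tmd_change * cort_frac
    fu_vals = base_vals + (
        delta_plane[:, :, None] * F["w_vert"][None, None, :]
    ).astype(np.float32)
    if apposition.existing_cortex_tmd_change:
        fu_vals += (
            apposition.existing_cortex_tmd_change
            * F["cov_peri"][:, :, None]
            * F["w_ep"][None, None, :]
        ).astype(np.float32)

    fine_vox_cc = np.prod(F["fine_spacing"])
    height_vert = spec.body_height - 2 * spec.endplate_width
    endo_slab_mm3 = float(endo_frac.sum()) * float(F["w_vert"].sum()) * fine_vox_cc
    peri_slab_mm3 = float(peri_frac.sum()) * float(F["w_vert"].sum()) * fine_vox_cc

    rng = np.random.default_rng(seed)
    seed_b, seed_f = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))

    origin = tuple(s / 2.0 for s in F["fine_spacing"])
    common = dict(spacing=F["fine_spacing"], origin=origin, calibrated=True)
    truth_meta = {
        "kind": "truth",
        "target_spacing": tuple(vs),
        "supersampling": supersampling,
        "phantom_center": F["center"],
        **meta,
    }
    base_truth = VoxelVolume(values=base_vals, meta=dict(truth_meta), **common)
    fu_truth = VoxelVolume(values=fu_vals, meta=dict(truth_meta), **common)
    baseline = acquire(base_truth, imaging, seed=seed_b)
    followup = acquire(fu_truth, imaging, seed=seed_f)

    a, b = spec.outer_semi_axes
    truth_record = {
        "outer_semi_axis_a_mm": a,
        "outer_semi_axis_b_mm": b,
        "body_height_mm": spec.body_height,
        "cortical_width_true_um": spec.cortical_width_true,
        "cortical_tmd": spec.cortical_tmd,
        "trabecular_bmd": spec.trabecular_bmd,
        "background_bmd": spec.background_bmd,
        "endplate_width_mm": spec.endplate_width,
        "endosteal_matrix_um": apposition.endosteal_matrix,
        "periosteal_matrix_um": apposition.periosteal_matrix,
        "mineralization_fraction": apposition.mineralization_fraction,
        "existing_cortex_tmd_change": apposition.existing_cortex_tmd_change,
        "scanner_preset": imaging.scanner_preset,
        "psf_sigma_inplane_mm": imaging.psf_sigma_inplane,
        "slice_thickness_mm": imaging.slice_thickness,
        "noise_sd": imaging.noise_sd,
        "seed": int(seed),
        "vertical_wall_height_mm": height_vert,
        "endo_slab_volume_mm3": endo_slab_mm3,
        "peri_slab_volume_mm3": peri_slab_mm3,
        "endo_slab_volume_analytic_mm3": (
            (ellipse_offset_area(a, b, -w) - ellipse_offset_area(a, b, -w - a_e))
            * height_vert if a_e > 0 else 0.0
        ),
        "peri_slab_volume_analytic_mm3": (
            (ellipse_offset_area(a, b, a_p) - ellipse_offset_area(a, b, 0.0))
            * height_vert if a_p > 0 else 0.0
        ),
        "truth_mass_baseline_mg": base_truth.total_mass_mg(),
        "truth_mass_followup_mg": fu_truth.total_mass_mg(),
    }
    return baseline, followup, truth_record


def save_truth_record(record: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(record, fh, indent=1, sort_keys=True)


def load_truth_record(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass
class ArmSpec:
    """Per-arm generating distributions for a simulated treatment cohort.

    Per-subject parameters are drawn from normal distributions truncated at
    physiologic bounds.  The endosteal/periosteal apposition split is drawn
    fully correlated so that the total-change SD equals
    ``endo_sd + peri_sd``.
    """

    name: str
    n: int
    width_mean: float = 359.0  # um
    width_sd: float = 0.0
    trabecular_mean: float = 115.0  # mg/cc
    trabecular_sd: float = 0.0
    endo_mean: float = 0.0  # um of matrix
    endo_sd: float = 0.0
    peri_mean: float = 0.0
    peri_sd: float = 0.0
    mineralization_fraction: float = 0.5

    def __post_init__(self):
        if self.n <= 0:
            raise CorticonError("arm size must be positive")


@dataclass
class SubjectTruth:
    subject_id: str
    arm: str
    phantom: PhantomSpec
    apposition: AppositionTruth
    imaging: ImagingSpec
    seed: int


_WIDTH_BOUNDS = (150.0, 800.0)  # um
_TRAB_BOUNDS = (20.0, 300.0)  # mg/cc


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Normal draws re-drawn until inside [lo, hi] (vectorized)."""
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def generate_cohort(
    arm_specs: list[ArmSpec],
    imaging_mix: list[tuple[ImagingSpec, int]],
    seed: int = 0,
    phantom_template: PhantomSpec | None = None,
):
    """Draw a reproducible longitudinal cohort with known ground truth.

    Returns ``(subjects, table)``: a list of :class:`SubjectTruth` (realize
    each with :func:`realize_subject`) and a pandas ground-truth table, one
    row per subject.
    """
    import pandas as pd

    total = sum(a.n for a in arm_specs)
    if sum(c for _, c in imaging_mix) != total:
        raise CorticonError("imaging_mix counts must sum to total cohort size")
    template = phantom_template or PhantomSpec()
    rng = np.random.default_rng(seed)

    scanners = [im for im, c in imaging_mix for _ in range(c)]
    rng.shuffle(scanners)

    subjects: list[SubjectTruth] = []
    rows = []
    idx = 0
    for arm in arm_specs:
        widths = _truncated_normal(rng, arm.width_mean, arm.width_sd, *_WIDTH_BOUNDS, size=arm.n)
        trabs = _truncated_normal(rng, arm.trabecular_mean, arm.trabecular_sd, *_TRAB_BOUNDS, size=arm.n)
        # fully correlated endo/peri draws: one standard-normal per subject
        u = rng.standard_normal(arm.n) if (arm.endo_sd or arm.peri_sd) else np.zeros(arm.n)
        endo = arm.endo_mean + arm.endo_sd * u
        peri = arm.peri_mean + arm.peri_sd * u
        # truncate totals at zero preserving the endo/peri proportion
        total_app = endo + peri
        neg = total_app < 0
        endo[neg] = 0.0
        peri[neg] = 0.0
        endo = np.clip(endo, 0.0, None)
        peri = np.clip(peri, 0.0, None)
        for j in range(arm.n):
            subject_seed = int(rng.integers(0, 2**31 - 1))
            spec = PhantomSpec(
                outer_semi_axes=template.outer_semi_axes,
                body_height=template.body_height,
                cortical_width_true=float(widths[j]),
                cortical_tmd=template.cortical_tmd,
                trabecular_bmd=float(trabs[j]),
                background_bmd=template.background_bmd,
                endplate_width=template.endplate_width,
                seed=subject_seed,
            )
            app = AppositionTruth(
                endosteal_matrix=float(endo[j]),
                periosteal_matrix=float(peri[j]),
                mineralization_fraction=arm.mineralization_fraction,
            )
            sid = f"{arm.name}-{j:03d}"
            subj = SubjectTruth(sid, arm.name, spec, app, scanners[idx], subject_seed)
            subjects.append(subj)
            rows.append({
                "subject_id": sid,
                "arm": arm.name,
                "cortical_width_true_um": spec.cortical_width_true,
                "trabecular_bmd": spec.trabecular_bmd,
                "endosteal_matrix_um": app.endosteal_matrix,
                "periosteal_matrix_um": app.periosteal_matrix,
                "total_apposition_um": app.endosteal_matrix + app.periosteal_matrix,
                "mineralization_fraction": app.mineralization_fraction,
                "scanner_preset": scanners[idx].scanner_preset,
                "psf_sigma_inplane_mm": scanners[idx].psf_sigma_inplane,
                "noise_sd": scanners[idx].noise_sd,
                "seed": subject_seed,
            })
            idx += 1
    return subjects, pd.DataFrame(rows)


def realize_subject(subject: SubjectTruth, supersampling: int = 4, margin: float = 3.0):
    """Render and acquire one cohort subject's longitudinal pair."""
    return make_longitudinal_pair(
        subject.phantom,
        subject.apposition,
        subject.imaging,
        seed=subject.seed,
        supersampling=supersampling,
        margin=margin,
    )
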