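import numpy as np
import pytest

import corticon as ct
from corticon.segmentation import CortexSegmentation, VoiConfig


@pytest.fixture(scope="session")
def ge_noiseless():
    return ct.ImagingSpec.preset("GE_BONE", noise_sd=0.0)


@pytest.fixture(scope="session")
def thin_spec():
    """Study-scale phantom: 359 um cortex over a 115 mg/cc plateau."""
    return ct.PhantomSpec()


@pytest.fixture(scope="session")
def thin_truth(thin_spec):
    return ct.render_phantom(thin_spec, supersampling=2)


@pytest.fixture(scope="session")
def thin_acq(thin_truth, ge_noiseless):
    return ct.acquire(thin_truth, ge_noiseless, seed=0)


@pytest.fixture(scope="session")
def thin_seg(thin_acq):
    return ct.segment_cortex(thin_acq)


@pytest.fixture(scope="session")
def thin_labels(thin_seg, thin_acq):
    return ct.local_thickness(thin_seg.cortical_mask, thin_acq.spacing)


@pytest.fixture(scope="session")
def thick_spec():
    """Resolvable 1.5 mm cortex on a larger body: boundary-accuracy oracle."""
    return ct.PhantomSpec(
        outer_semi_axes=(12.0, 10.0), body_height=8.0, cortical_width_true=1500.0
    )


@pytest.fixture(scope="session")
def thick_acq(thick_spec):
    imaging = ct.ImagingSpec.preset("SIEMENS_B70S", noise_sd=0.0)
    return ct.acquire(ct.render_phantom(thick_spec, supersampling=2), imaging, seed=0)


@pytest.fixture(scope="session")
def thick_seg(thick_acq):
    return ct.segment_cortex(thick_acq)


def make_fake_seg(distance_field, spacing, vertical_slices=None):
    """Minimal segmentation carrying a hand-built mid-surface distance field."""
    nz = distance_field.shape[2]
    vert = np.arange(nz) if vertical_slices is None else np.asarray(vertical_slices)
    dummy = np.zeros((nz, 4))
    return CortexSegmentation(
        centroid=(0.0, 0.0),
        angles=np.linspace(0, 2 * np.pi, 4, endpoint=False),
        body_slices=np.arange(nz),
        vertical_slices=vert,
        r_peri=dummy + 2.0,
        r_endo=dummy + 1.0,
        fields={"mid": np.asarray(distance_field, dtype=np.float32)},
        cortical_mask=np.zeros(distance_field.shape, dtype=bool),
        voi_labels=np.zeros(distance_field.shape, dtype=np.uint8),
        spacing=spacing,
        config=VoiConfig(),
    )


def uniform_profile(value=200.0, inner=-4.0, outer=3.0, thickness=0.2, count=100):
    edges = inner + thickness * np.arange(int(round((outer - inner) / thickness)) + 1)
    n = edges.size - 1
    return ct.RadialProfile(
        bin_edges=edges,
        mean_bmd=np.full(n, float(value)),
        count=np.full(n, count, dtype=int),
        voxel_volume_mm3=0.012,
    )


def synthetic_profile(model, apposition=None, inner=-4.0, outer=3.0, thickness=0.2,
                      count=100, noise_sd=0.0, rng=None):
    """Profile sampled exactly from the forward model (optionally noisy)."""
    prof = uniform_profile(0.0, inner, outer, thickness, count)
    y = ct.forward_model(model, apposition, prof.bin_centers)
    if noise_sd > 0:
        rng = rng or np.random.default_rng(0)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return prof.with_values(y)
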