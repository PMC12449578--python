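import numpy as np
import pytest

import corticon as ct
from corticon.errors import CorticonError, ResolutionError
from corticon.phantoms import (
    ellipse_offset_area,
    ellipse_signed_distance,
    load_truth_record,
    save_truth_record,
)


class TestRenderPhantom:
    def test_piecewise_values_at_shell_and_center(self):
        spec = ct.PhantomSpec(trabecular_bmd=100.0, cortical_width_true=360.0)
        vol = ct.render_phantom(spec, supersampling=4)
        a, _ = spec.outer_semi_axes
        cx, cy, cz = vol.meta["phantom_center"]
        sx, sy, sz = vol.spacing
        # voxel center nearest the shell mid-band on the +x axis
        ix = int(round((cx + a - spec.cortical_width_mm / 2) / sx - 0.5))
        iy = int(round(cy / sy - 0.5))
        iz = vol.shape[2] // 2
        assert vol.values[ix, iy, iz] == pytest.approx(1100.0)
        ic = int(round(cx / sx - 0.5))
        assert vol.values[ic, iy, iz] == pytest.approx(100.0)

    def test_zero_width_rejected(self):
        with pytest.raises(CorticonError):
            ct.PhantomSpec(cortical_width_true=0.0)

    def test_width_below_fine_voxel_rejected(self):
        spec = ct.PhantomSpec(cortical_width_true=150.0)
        with pytest.raises(ResolutionError):
            ct.render_phantom(spec, supersampling=1)

    def test_cross_section_mean_matches_analytic_mix(self):
        spec = ct.PhantomSpec(trabecular_bmd=100.0)
        vol = ct.render_phantom(spec, supersampling=2)
        a, b = spec.outer_semi_axes
        w = spec.cortical_width_mm
        area_total = ellipse_offset_area(a, b, 0.0)
        area_inner = ellipse_offset_area(a, b, -w)
        expected = (1100.0 * (area_total - area_inner) + 100.0 * area_inner) / area_total
        iz = vol.shape[2] // 2  # mid-body slice, vertical wall region
        sx, sy, _ = vol.spacing
        measured = vol.values[:, :, iz].sum(dtype=np.float64) * sx * sy / area_total
        assert measured == pytest.approx(expected, rel=0.005)

    def test_ellipse_signed_distance_sign_and_axis_values(self):
        d = ellipse_signed_distance(np.array([0.0, 9.0, 12.0]), np.zeros(3), 9.0, 7.0)
        assert d[1] == pytest.approx(0.0, abs=1e-6)
        assert d[2] == pytest.approx(3.0, abs=1e-5)
        assert d[0] < 0


class TestAcquire:
    def test_identity_when_matched_grids_no_blur(self):
        spec = ct.PhantomSpec()
        truth = ct.render_phantom(spec, supersampling=1)
        imaging = ct.ImagingSpec(
            psf_sigma_inplane=0.0, psf_sigma_z=0.0, slice_thickness=0.3, noise_sd=0.0
        )
        out = ct.acquire(truth, imaging, seed=0)
        np.testing.assert_allclose(out.values, truth.values, atol=1e-6)

    def test_uniform_input_stays_uniform(self, ge_noiseless):
        vol = ct.VoxelVolume(
            values=np.full((40, 40, 24), 137.0, dtype=np.float32),
            spacing=(0.1, 0.1, 0.15),
        )
        out = ct.acquire(vol, ge_noiseless, seed=0)
        np.testing.assert_allclose(out.values, 137.0, atol=1e-3)

    def test_mass_conservation_under_blur_and_resample(self, thin_truth, ge_noiseless):
        acq = ct.acquire(thin_truth, ge_noiseless, seed=0)
        m0 = thin_truth.total_mass_mg()
        assert abs(acq.total_mass_mg() - m0) / m0 < 1e-3

    def test_negative_noise_rejected(self):
        with pytest.raises(CorticonError):
            ct.ImagingSpec(noise_sd=-1.0)

    def test_seed_determinism(self, thin_truth):
        imaging = ct.ImagingSpec.preset("GE_BONE", noise_sd=25.0)
        a = ct.acquire(thin_truth, imaging, seed=11)
        b = ct.acquire(thin_truth, imaging, seed=11)
        np.testing.assert_array_equal(a.values, b.values)
        c = ct.acquire(thin_truth, imaging, seed=12)
        assert not np.array_equal(a.values, c.values)


class TestLongitudinalPair:
    def test_zero_apposition_identical_timepoints(self):
        spec = ct.PhantomSpec(outer_semi_axes=(6.0, 5.0), body_height=8.0)
        imaging = ct.ImagingSpec.preset("GE_BONE", noise_sd=0.0)
        base, follow, _ = ct.make_longitudinal_pair(
            spec, ct.AppositionTruth(), imaging, seed=0, supersampling=2
        )
        np.testing.assert_array_equal(base.values, follow.values)

    def test_mass_excess_equals_slab_density_times_volume(self):
        spec = ct.PhantomSpec(outer_semi_axes=(6.0, 5.0), body_height=8.0)
        app = ct.AppositionTruth(endosteal_matrix=200.0, mineralization_fraction=0.5)
        imaging = ct.ImagingSpec.preset("GE_BONE", noise_sd=0.0)
        _, _, rec = ct.make_longitudinal_pair(spec, app, imaging, seed=0, supersampling=2)
        dm = rec["truth_mass_followup_mg"] - rec["truth_mass_baseline_mg"]
        expected = 550.0e-3 * rec["endo_slab_volume_mm3"]
        assert dm == pytest.approx(expected, rel=1e-6)
        # voxelized slab volume agrees with the analytic offset-annulus
        assert rec["endo_slab_volume_mm3"] == pytest.approx(
            rec["endo_slab_volume_analytic_mm3"], rel=0.005
        )

    def test_truth_record_roundtrip(self, tmp_path):
        spec = ct.PhantomSpec(outer_semi_axes=(6.0, 5.0), body_height=8.0)
        app = ct.AppositionTruth(endosteal_matrix=120.0, periosteal_matrix=40.0)
        imaging = ct.ImagingSpec.preset("PHILIPS_D", noise_sd=10.0)
        _, _, rec = ct.make_longitudinal_pair(spec, app, imaging, seed=3, supersampling=2)
        path = tmp_path / "truth.json"
        save_truth_record(rec, path)
        assert load_truth_record(path) == rec

    def test_cavity_infill_rejected(self):
        spec = ct.PhantomSpec(outer_semi_axes=(6.0, 5.0), body_height=8.0)
        app = ct.AppositionTruth(endosteal_matrix=5000.0)
        with pytest.raises(CorticonError):
            ct.make_longitudinal_pair(
                spec, app, ct.ImagingSpec.preset("GE_BONE"), seed=0, supersampling=2
            )


class TestGenerateCohort:
    def _arms(self, sd=0.0):
        return [
            ct.ArmSpec(name="a", n=3, width_mean=350, width_sd=sd,
                       endo_mean=100, endo_sd=sd, peri_mean=40, peri_sd=sd / 2),
            ct.ArmSpec(name="b", n=2, width_mean=360, width_sd=sd),
        ]

    def _mix(self, n):
        return [(ct.ImagingSpec.preset("GE_BONE"), n)]

    def test_same_seed_identical_truth_tables(self):
        import pandas.testing as pdt

        _, t1 = ct.generate_cohort(self._arms(5.0), self._mix(5), seed=42)
        _, t2 = ct.generate_cohort(self._arms(5.0), self._mix(5), seed=42)
        pdt.assert_frame_equal(t1, t2)

    def test_zero_sd_gives_identical_subjects(self):
        _, table = ct.generate_cohort(self._arms(0.0), self._mix(5), seed=1)
        a = table[table.arm == "a"]
        assert a["cortical_width_true_um"].nunique() == 1
        assert a["endosteal_matrix_um"].nunique() == 1

    def test_large_cohort_mean_within_3_se(self):
        arms = [ct.ArmSpec(name="big", n=200, width_mean=360.0, width_sd=40.0)]
        _, table = ct.generate_cohort(arms, self._mix(200), seed=7)
        se = 40.0 / np.sqrt(200)
        assert abs(table["cortical_width_true_um"].mean() - 360.0) < 3 * se

    def test_mix_count_mismatch_rejected(self):
        with pytest.raises(CorticonError):
            ct.generate_cohort(self._arms(), self._mix(4), seed=0)

    def test_nonpositive_arm_rejected(self):
        with pytest.raises(CorticonError):
            ct.ArmSpec(name="x", n=0)
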