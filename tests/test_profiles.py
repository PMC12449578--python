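import numpy as np
import pytest

import corticon as ct
from corticon.errors import CorticonError

from conftest import make_fake_seg, uniform_profile


SPACING = (0.2, 0.2, 0.3)


def _random_seg_and_volume(seed=0, shape=(6, 5, 4)):
    rng = np.random.default_rng(seed)
    d = rng.uniform(-4.5, 3.5, shape)
    vals = rng.uniform(0, 500, shape)
    seg = make_fake_seg(d, SPACING)
    vol = ct.VoxelVolume(values=vals, spacing=SPACING)
    return seg, vol, d, vals


def test_uniform_volume_gives_flat_profile(thin_acq, thin_seg):
    vol = thin_acq.copy(values=np.full(thin_acq.shape, 222.0, dtype=np.float32))
    prof = ct.extract_profile(vol, thin_seg)
    populated = prof.count > 0
    assert populated.any()
    np.testing.assert_allclose(prof.mean_bmd[populated], 222.0, atol=1e-4)


def test_binning_convention_half_open():
    """A voxel at +0.31 mm with 0.2 mm layers anchored at 0 lands in [0.2, 0.4)."""
    d = np.full((1, 1, 1), 0.31)
    seg = make_fake_seg(d, SPACING)
    vol = ct.VoxelVolume(values=np.full((1, 1, 1), 99.0), spacing=SPACING)
    prof = ct.extract_profile(vol, seg)
    (idx,) = np.flatnonzero(prof.count)
    assert prof.bin_edges[idx] == pytest.approx(0.2)
    assert prof.bin_edges[idx + 1] == pytest.approx(0.4)
    # exactly on an edge belongs to the upper bin
    prof_edge = ct.extract_profile(vol.copy(), make_fake_seg(np.full((1, 1, 1), 0.2), SPACING))
    (idx_e,) = np.flatnonzero(prof_edge.count)
    assert prof_edge.bin_edges[idx_e] == pytest.approx(0.2)


def test_per_bin_means_match_bruteforce_loop():
    seg, vol, d, vals = _random_seg_and_volume(3)
    cfg = ct.ProfileConfig()
    prof = ct.extract_profile(vol, seg, cfg)
    edges = cfg.edges
    for i in range(edges.size - 1):
        sel = (d >= edges[i]) & (d < edges[i + 1])
        assert prof.count[i] == sel.sum()
        if sel.any():
            assert prof.mean_bmd[i] == pytest.approx(vals[sel].mean(), rel=1e-12)


def test_no_voxel_lost_or_double_counted():
    seg, vol, d, _ = _random_seg_and_volume(9)
    cfg = ct.ProfileConfig()
    prof = ct.extract_profile(vol, seg, cfg)
    in_range = (d >= cfg.range_inner) & (d < cfg.edges[-1])
    assert prof.count.sum() == in_range.sum()


def test_axis_permutation_invariance():
    seg, vol, d, vals = _random_seg_and_volume(5, shape=(6, 6, 6))
    prof = ct.extract_profile(vol, seg)
    perm_seg = make_fake_seg(d.transpose(1, 0, 2), SPACING)
    perm_vol = ct.VoxelVolume(values=vals.transpose(1, 0, 2), spacing=SPACING)
    prof_p = ct.extract_profile(perm_vol, perm_seg)
    np.testing.assert_allclose(prof.mean_bmd, prof_p.mean_bmd, equal_nan=True)
    np.testing.assert_array_equal(prof.count, prof_p.count)


class TestZoneSummary:
    def test_constant_profile_zones(self):
        prof = uniform_profile(150.0)
        zones = ct.zone_summary(prof, ridge_position=0.0)
        for name in ("PERIOSTEAL", "CENTRAL", "ENDOSTEAL"):
            assert zones.bmd[name] == pytest.approx(150.0)
            assert zones.bmc[name] == pytest.approx(150.0 * 0.4 / 10.0)
        assert zones.bmd["SUBCORTICAL"] == pytest.approx(150.0)

    def test_ridge_shift_by_full_bin_translates_zones(self):
        rng = np.random.default_rng(2)
        prof = uniform_profile(0.0)
        prof = prof.with_values(rng.uniform(50, 400, prof.mean_bmd.size))
        z0 = ct.zone_summary(prof, ridge_position=0.0)
        z1 = ct.zone_summary(prof, ridge_position=0.2)
        rolled = prof.with_values(np.roll(prof.mean_bmd, -1))
        z0_rolled = ct.zone_summary(rolled, ridge_position=0.0)
        for name in ("PERIOSTEAL", "CENTRAL", "ENDOSTEAL", "SUBCORTICAL"):
            assert z1.bmd[name] == pytest.approx(z0_rolled.bmd[name], rel=1e-9)

    def test_zone_bmc_matches_independent_quadrature(self):
        rng = np.random.default_rng(8)
        prof = uniform_profile(0.0)
        prof = prof.with_values(rng.uniform(0, 500, prof.mean_bmd.size))
        ridge = 0.07
        zones = ct.zone_summary(prof, ridge)
        cfg = ct.ZoneConfig()
        for name, (lo, hi) in (
            ("PERIOSTEAL", cfg.periosteal),
            ("CENTRAL", cfg.central),
            ("ENDOSTEAL", cfg.endosteal),
            ("SUBCORTICAL", cfg.subcortical),
        ):
            a, b = ridge + lo, ridge + hi
            total = 0.0
            for i in range(prof.bin_edges.size - 1):
                left = max(prof.bin_edges[i], a)
                right = min(prof.bin_edges[i + 1], b)
                if right > left:
                    total += prof.mean_bmd[i] * (right - left)
            assert zones.bmc[name] == pytest.approx(total / 10.0, abs=1e-9)

    def test_zone_beyond_profile_range_errors(self):
        prof = uniform_profile(100.0)
        with pytest.raises(CorticonError):
            ct.zone_summary(prof, ridge_position=2.9)
        with pytest.raises(CorticonError):
            ct.zone_summary(prof, ridge_position=5.0)


def test_plot_profiles_writes_figure(tmp_path):
    prof = uniform_profile(100.0)
    out = tmp_path / "profiles.png"
    ct.plot_profiles({"baseline": prof}, path=out)
    assert out.exists() and out.stat().st_size > 0
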