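import numpy as np
import pytest
from scipy.special import ndtr

import corticon as ct
from corticon.errors import DegenerateModelError, FitError
from corticon.icon import AppositionModel, CortexModel

from conftest import synthetic_profile, uniform_profile


def _model(center=0.1, width=0.359, sigma=0.55, plateau=100.0, soft=0.0):
    return CortexModel(
        center=center, width=width, sigma=sigma, plateau=plateau,
        soft_tissue=soft, converged=True,
    )


def _numerical_convolution(model, apposition, x_eval, dx=0.001):
    """Brute-force oracle: blur the unblurred piecewise profile with a
    sampled Gaussian, using fractional edge coverage per cell."""
    x = np.arange(-12.0, 12.0, dx) + dx / 2

    def cov(lo, hi):
        return np.clip((np.minimum(x + dx / 2, hi) - np.maximum(x - dx / 2, lo)) / dx, 0, 1)

    e, p = model.endosteal_edge, model.periosteal_edge
    truth = (
        model.plateau * cov(-np.inf, e)
        + model.tmd_ref * cov(e, p)
        + model.soft_tissue * cov(p, np.inf)
    )
    if apposition is not None:
        rho = apposition.mineralization_fraction * model.tmd_ref
        truth += rho * cov(e - apposition.endosteal_width, e)
        truth += rho * cov(p, p + apposition.periosteal_width)
    m = int(np.ceil(8 * model.sigma / dx))
    kx = (np.arange(2 * m + 1) - m) * dx
    k = np.exp(-0.5 * (kx / model.sigma) ** 2)
    k /= k.sum()
    blurred = np.convolve(truth, k, mode="same")
    return x, blurred, np.interp(x_eval, x, blurred)


class TestForwardModel:
    def test_small_sigma_limit_inside_band(self):
        m = _model(sigma=1e-6)
        assert ct.forward_model(m, None, [m.center])[0] == pytest.approx(1100.0)

    def test_asymptotic_levels(self):
        m = _model(plateau=120.0, soft=5.0)
        y = ct.forward_model(m, None, [-30.0, 30.0])
        assert y[0] == pytest.approx(120.0)
        assert y[1] == pytest.approx(5.0)

    def test_matches_numerical_convolution_oracle(self):
        m = _model()
        app = AppositionModel(endosteal_width=0.15, periosteal_width=0.08,
                              mineralization_fraction=0.5)
        x_grid, blurred, _ = _numerical_convolution(m, app, np.zeros(1))
        pred = ct.forward_model(m, app, x_grid)
        sel = (x_grid > -6) & (x_grid < 6)
        assert np.abs(pred[sel] - blurred[sel]).max() < 1e-3
        # background-subtracted band mass matches to 1e-6
        bg = m.soft_tissue + (m.plateau - m.soft_tissue) * ndtr(
            (m.endosteal_edge - x_grid) / m.sigma
        )
        dx = x_grid[1] - x_grid[0]
        num = np.sum((blurred - bg)[sel]) * dx
        ana = np.sum((pred - bg)[sel]) * dx
        assert ana == pytest.approx(num, rel=1e-6)

    def test_zero_sigma_rejected(self):
        with pytest.raises(FitError):
            ct.forward_model(_model(sigma=0.0), None, [0.0])


class TestFitBaseline:
    def test_roundtrip_recovers_width_within_1pct(self):
        truth = _model(center=0.12, width=0.359, sigma=0.55, plateau=100.0)
        prof = synthetic_profile(truth)
        fit = ct.fit_baseline(prof, init_width=0.32, scanner_sigma=0.55)
        assert fit.width == pytest.approx(0.359, rel=0.01)
        assert fit.sigma == pytest.approx(0.55, rel=0.05)
        assert fit.plateau == pytest.approx(100.0, abs=3.0)

    def test_pure_plateau_flagged_degenerate(self):
        prof = uniform_profile(0.0)
        x = prof.bin_centers
        esf_only = 120.0 * ndtr((0.0 - x) / 0.55)
        prof = prof.with_values(esf_only)
        fit = ct.fit_baseline(prof, init_width=0.3, scanner_sigma=0.55)
        assert fit.degenerate
        with pytest.raises(DegenerateModelError):
            ct.dcctth(fit)

    def test_solution_beats_grid_scan(self):
        """Optimizer objective no worse than a 50x50 (w, c) grid scan."""
        truth = _model()
        prof = synthetic_profile(truth, noise_sd=3.0, rng=np.random.default_rng(1))
        fit = ct.fit_baseline(prof, init_width=0.3, scanner_sigma=0.55)
        x = prof.bin_centers
        y = prof.mean_bmd
        wts = np.sqrt(prof.count / prof.count.mean())

        def sse(c, w):
            m = CortexModel(center=c, width=w, sigma=fit.sigma,
                            plateau=fit.plateau, soft_tissue=fit.soft_tissue)
            return np.sum(((ct.forward_model(m, None, x) - y) * wts) ** 2)

        best_fit = sse(fit.center, fit.width)
        grid = [
            sse(c, w)
            for c in np.linspace(-1.0, 1.0, 50)
            for w in np.linspace(0.05, 1.0, 50)
        ]
        assert best_fit <= min(grid) + 1e-9

    def test_sigma_misspecification_robustness(self):
        """Width moves <10% when the assumed PSF is off by +-10%."""
        for sigma_true in (0.39, 0.55, 0.61):
            truth = _model(sigma=sigma_true)
            prof = synthetic_profile(truth)
            for factor in (0.9, 1.1):
                fit = ct.fit_baseline(prof, init_width=0.3,
                                      scanner_sigma=factor * sigma_true)
                assert abs(fit.width - truth.width) / truth.width < 0.10

    def test_mass_conservation_of_fit(self):
        """Fitted w x tmd_ref equals the background-subtracted integral."""
        truth = _model(center=0.0, width=0.42, sigma=0.61, plateau=130.0)
        prof = synthetic_profile(truth)
        fit = ct.fit_baseline(prof, init_width=0.40, scanner_sigma=0.61)
        resid = ct.subtract_spongiosa(prof, fit)
        integral = np.nansum(resid.mean_bmd) * prof.layer_thickness
        assert fit.width * (fit.tmd_ref - fit.soft_tissue) == pytest.approx(
            integral, rel=0.02
        )


class TestSubtractSpongiosa:
    def test_pure_esf_leaves_zero_residual(self):
        m = _model()
        prof = uniform_profile(0.0)
        esf = m.soft_tissue + (m.plateau - m.soft_tissue) * ndtr(
            (m.endosteal_edge - prof.bin_centers) / m.sigma
        )
        resid = ct.subtract_spongiosa(prof.with_values(esf), m)
        np.testing.assert_allclose(resid.mean_bmd, 0.0, atol=1e-12)

    def test_subtract_then_readd_is_identity(self):
        m = _model()
        prof = synthetic_profile(m)
        resid = ct.subtract_spongiosa(prof, m)
        esf = prof.mean_bmd - resid.mean_bmd
        np.testing.assert_allclose(resid.mean_bmd + esf, prof.mean_bmd, atol=1e-12)

    def test_endosteal_tail_centered_on_zero(self):
        m = _model(center=0.0)
        rng = np.random.default_rng(42)
        noise_sd = 5.0
        count = 400
        prof = synthetic_profile(m, noise_sd=noise_sd, count=count, rng=rng)
        fit = ct.fit_baseline(prof, init_width=0.3, scanner_sigma=0.55)
        resid = ct.subtract_spongiosa(prof, fit)
        tail = resid.bin_centers < fit.endosteal_edge - 3 * fit.sigma
        assert tail.sum() >= 3
        se = noise_sd / np.sqrt(tail.sum())
        assert abs(np.nanmean(resid.mean_bmd[tail])) < 3 * se


class TestFitApposition:
    def test_unchanged_profile_gives_zero_apposition(self):
        base = _model()
        prof = synthetic_profile(base)
        app = ct.fit_apposition(base, prof, f=0.5)
        assert app.endosteal_width == pytest.approx(0.0, abs=1e-6)
        assert app.periosteal_width == pytest.approx(0.0, abs=1e-6)

    def test_roundtrip_recovers_endosteal_slab(self):
        base = _model()
        truth_app = AppositionModel(endosteal_width=0.2, periosteal_width=0.0,
                                    mineralization_fraction=0.5)
        prof = synthetic_profile(base, truth_app)
        app = ct.fit_apposition(base, prof, f=0.5)
        assert app.endosteal_width == pytest.approx(0.2, rel=0.02)
        assert abs(app.periosteal_width) < 0.01

    def test_exact_inverse_scaling_with_mineralization(self):
        base = _model()
        truth_app = AppositionModel(endosteal_width=0.15, periosteal_width=0.06,
                                    mineralization_fraction=0.5)
        prof = synthetic_profile(base, truth_app, noise_sd=4.0,
                                 rng=np.random.default_rng(3))
        app_half = ct.fit_apposition(base, prof, f=0.5)
        app_full = ct.fit_apposition(base, prof, f=1.0)
        assert app_full.total_width == pytest.approx(app_half.total_width / 2, rel=1e-9)
        assert app_full.endosteal_width == pytest.approx(
            app_half.endosteal_width / 2, rel=1e-9
        )


class TestDcctth:
    def test_unit_conversion(self):
        assert ct.dcctth(_model(width=0.359)) == pytest.approx(359.0)

    def test_followup_adds_total_apposition(self):
        base = _model(width=0.364)
        app = AppositionModel(endosteal_width=0.194 * 0.7,
                              periosteal_width=0.194 * 0.3)
        assert ct.dcctth_followup(base, app) == pytest.approx(558.0)

    def test_zero_apposition_keeps_baseline(self):
        base = _model(width=0.40)
        app = AppositionModel(endosteal_width=0.0, periosteal_width=0.0)
        assert ct.dcctth_followup(base, app) == ct.dcctth(base)
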