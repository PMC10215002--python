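import math

import numpy as np
import pytest

from seedperturb import (
    FitError,
    PeakModel,
    draw_truth,
    evaluate_model,
    fit_peak,
    fwhm,
    locate_peak,
    peak_amplitude,
    summarize_cluster,
)
from seedperturb.peaks import results_frame
from seedperturb.profiles import PerturbationProfile
from conftest import profile_from_model

# film-protocol bounds used by the noisy recovery studies: widths limited to
# the resolvable instrument regime, offset pinned near the normalized baseline
PROTOCOL_BOUNDS = {"width": (0.45, 2.6), "offset": (-2.0, 2.0), "mu_shift": 0.3}


def scan_oracle_fwhm(model, grid_mm=1e-5):
    """Independent FWHM oracle: dense-grid scan for the half crossing."""
    half = 0.5 * peak_amplitude(model)
    u = np.arange(0.0, 0.75 * max(model.w_g, model.w_l) + grid_mm, grid_mm)
    vals = np.abs(evaluate_model(model, model.mu + u) - model.f0)
    below = np.where(vals < half)[0]
    i = below[0]
    # linear interpolation between the bracketing grid points
    frac = (vals[i - 1] - half) / (vals[i - 1] - vals[i])
    return 2.0 * (u[i - 1] + frac * grid_mm)


class TestEvaluateModel:
    def test_gaussian_half_maximum(self):
        m = PeakModel(f0=3.0, m=0.0, h_g=10.0, h_l=0.0, w_g=1.6, w_l=1.0, mu=0.5, sign=1)
        for x in (m.mu - m.w_g / 2, m.mu + m.w_g / 2):
            assert evaluate_model(m, x) == pytest.approx(3.0 + 5.0, abs=1e-12)

    def test_lorentzian_half_maximum(self):
        m = PeakModel(f0=-1.0, m=1.0, h_g=0.0, h_l=8.0, w_g=1.0, w_l=0.8, mu=0.0, sign=1)
        for x in (-m.w_l / 2, m.w_l / 2):
            assert evaluate_model(m, x) == pytest.approx(-1.0 + 4.0, abs=1e-12)

    def test_peak_identity_at_mu(self, rng):
        for _ in range(20):
            m = PeakModel(
                f0=rng.uniform(-5, 5),
                m=rng.uniform(0, 1),
                h_g=rng.uniform(0, 20),
                h_l=rng.uniform(0, 20),
                w_g=rng.uniform(0.2, 5),
                w_l=rng.uniform(0.2, 5),
                mu=rng.uniform(-2, 2),
                sign=int(rng.choice([-1, 1])),
            )
            expected = m.f0 + m.sign * ((1 - m.m) * m.h_g + m.m * m.h_l)
            assert evaluate_model(m, m.mu) == pytest.approx(expected, abs=1e-12)

    def test_sign_flips_perturbation(self):
        up = PeakModel(f0=0, m=0.5, h_g=10, h_l=10, w_g=1, w_l=1, mu=0, sign=1)
        dn = PeakModel(f0=0, m=0.5, h_g=10, h_l=10, w_g=1, w_l=1, mu=0, sign=-1)
        x = np.linspace(-3, 3, 31)
        assert np.allclose(evaluate_model(up, x), -evaluate_model(dn, x))


class TestFwhm:
    def test_pure_gaussian_limit(self):
        m = PeakModel(f0=0, m=0.0, h_g=10, h_l=10, w_g=1.7, w_l=0.6, mu=0, sign=1)
        assert fwhm(m) == pytest.approx(1.7, abs=1e-6)

    def test_pure_lorentzian_limit(self):
        m = PeakModel(f0=0, m=1.0, h_g=10, h_l=10, w_g=1.7, w_l=0.8, mu=0, sign=-1)
        assert fwhm(m) == pytest.approx(0.8, abs=1e-6)

    def test_equal_mixture_against_scan_oracle(self):
        m = PeakModel(f0=0, m=0.5, h_g=8, h_l=8, w_g=2.0, w_l=1.0, mu=0, sign=1)
        assert fwhm(m) == pytest.approx(scan_oracle_fwhm(m), abs=1e-4)

    def test_bracketed_by_component_widths(self, rng):
        for _ in range(30):
            m = PeakModel(
                f0=0,
                m=rng.uniform(0.05, 0.95),
                h_g=rng.uniform(1, 20),
                h_l=rng.uniform(1, 20),
                w_g=rng.uniform(0.3, 3),
                w_l=rng.uniform(0.3, 3),
                mu=0,
                sign=1,
            )
            w = fwhm(m)
            assert min(m.w_g, m.w_l) - 1e-6 <= w <= max(m.w_g, m.w_l) + 1e-6

    def test_monotone_in_lorentzian_ratio(self):
        # equal heights, W_G < W_L: more Lorentzian weight widens the composite
        prev = None
        for m_ratio in np.linspace(0.0, 1.0, 11):
            m = PeakModel(f0=0, m=m_ratio, h_g=10, h_l=10, w_g=0.8, w_l=2.0, mu=0, sign=1)
            w = fwhm(m)
            assert w == pytest.approx(scan_oracle_fwhm(m), abs=1e-4)
            if prev is not None:
                assert w >= prev - 1e-9
            prev = w

    def test_zero_amplitude_errors(self):
        m = PeakModel(f0=0, m=0.0, h_g=0.0, h_l=0.0, w_g=1, w_l=1, mu=0, sign=1)
        with pytest.raises(FitError, match="amplitude"):
            fwhm(m)


class TestLocatePeak:
    def test_positive_bump_at_zero(self):
        m = PeakModel(f0=0, m=0.0, h_g=8, h_l=8, w_g=1.5, w_l=1, mu=0, sign=1)
        mu0, sign = locate_peak(profile_from_model(m))
        assert mu0 == 0.0 and sign == 1

    def test_negative_dip_off_center(self):
        m = PeakModel(f0=0, m=0.2, h_g=11, h_l=11, w_g=1.0, w_l=0.8, mu=1.2, sign=-1)
        mu0, sign = locate_peak(profile_from_model(m))
        assert mu0 == pytest.approx(1.2, abs=1e-9) and sign == -1

    def test_tie_breaks_toward_negative_of_equal_magnitude(self):
        # two exactly equal bumps at +/-0.5: tie rule picks smaller |x|,
        # and between equal |x| the more negative position
        x = np.arange(-20, 21) * 0.1
        d = np.zeros(x.size)
        d[np.isclose(x, -0.5)] = 5.0
        d[np.isclose(x, 0.5)] = 5.0
        prof = PerturbationProfile(x, d, 0.1)
        mu0, sign = locate_peak(prof)
        # oracle: exhaustive scan of the documented rule
        mag = np.abs(d)
        cands = np.where(mag == mag.max())[0]
        expected = x[cands[np.argmin(np.abs(x[cands]))]]
        assert mu0 == expected == -0.5

    def test_all_zero_errors(self):
        prof = PerturbationProfile(np.arange(-5, 6) * 0.5, np.zeros(11), 0.5)
        with pytest.raises(FitError, match="no peak"):
            locate_peak(prof)

    def test_search_window_restricts(self):
        x = np.arange(-50, 51) * 0.1
        d = np.zeros(x.size)
        d[np.isclose(x, 4.0)] = 10.0
        d[np.isclose(x, 0.5)] = 5.0
        prof = PerturbationProfile(x, d, 0.1)
        mu0, _ = locate_peak(prof, search_half_width_mm=2.5)
        assert mu0 == 0.5


class TestFitPeak:
    def test_noiseless_known_model_round_trip(self):
        truth = PeakModel(f0=0.0, m=0.4, h_g=8.0, h_l=8.0, w_g=1.6, w_l=0.9, mu=0.0, sign=1)
        prof = profile_from_model(truth)
        mu0, sign = locate_peak(prof, 2.5)
        fit = fit_peak(prof, mu0, sign, seed=0)
        assert fit.dose_difference == pytest.approx(8.0, abs=1e-3)
        assert fit.fwhm == pytest.approx(scan_oracle_fwhm(truth), abs=1e-3)
        assert fit.converged

    def test_all_zero_profile_null_fit(self):
        x = np.arange(-30, 31) * 0.1
        prof = PerturbationProfile(x, np.zeros(x.size), 0.1)
        fit = fit_peak(prof, 0.0, +1, seed=0)
        assert abs(fit.dose_difference) < 1e-6
        assert fit.converged

    def test_insufficient_points_errors(self):
        x = np.arange(-3, 4) * 1.0
        prof = PerturbationProfile(x, np.ones(x.size), 1.0)
        with pytest.raises(FitError, match="insufficient"):
            fit_peak(prof, 0.0, +1, window_half_width_mm=2.5)

    def test_sign_correctness_build_down(self):
        truth = PeakModel(f0=0.0, m=0.3, h_g=11.3, h_l=11.3, w_g=0.8, w_l=0.8, mu=0.0, sign=-1)
        prof = profile_from_model(truth)
        mu0, sign = locate_peak(prof, 2.5)
        assert sign == -1
        fit = fit_peak(prof, mu0, sign, seed=0)
        assert fit.dose_difference == pytest.approx(-11.3, abs=1e-3)

    def test_sse_not_worse_than_truth_on_noiseless_data(self, rng):
        for i in range(10):
            truth = draw_truth(rng, 1, amplitude_range=(5, 20))[0]
            prof = profile_from_model(truth)
            mu0, sign = locate_peak(prof, 2.5)
            fit = fit_peak(prof, mu0, sign, seed=i)
            # truth has SSE exactly 0 inside the window
            assert fit.sse <= 1e-12

    def test_deterministic_given_seed(self, rng):
        truth = PeakModel(f0=0.5, m=0.6, h_g=9, h_l=9, w_g=1.2, w_l=1.8, mu=0.1, sign=1)
        x = np.arange(-40, 41) * 0.1
        d = evaluate_model(truth, x) + rng.normal(0, 2.0, x.size)
        prof = PerturbationProfile(x, d, 0.1)
        f1 = fit_peak(prof, 0.1, 1, seed=7)
        f2 = fit_peak(prof, 0.1, 1, seed=7)
        assert f1.dose_difference == f2.dose_difference
        assert f1.model == f2.model

    def test_noisy_height_bias_within_band(self):
        # bias check: 2% profile noise, true height 10%
        truth = PeakModel(f0=0.0, m=0.4, h_g=10.0, h_l=10.0, w_g=1.6, w_l=0.9, mu=0.0, sign=1)
        x = np.arange(-60, 61) * 0.1
        clean = evaluate_model(truth, x)
        errs = []
        for s in range(100):
            rng = np.random.default_rng(2000 + s)
            prof = PerturbationProfile(x, clean + 2.0 * rng.standard_normal(x.size), 0.1)
            mu0, sign = locate_peak(prof, 2.5)
            fit = fit_peak(prof, mu0, sign, bounds=PROTOCOL_BOUNDS, seed=s)
            errs.append(fit.dose_difference - 10.0)
        assert abs(np.mean(errs)) < 1.5


class TestSummarizeCluster:
    def _fit(self, dd, w=1.0):
        model = PeakModel.from_amplitudes(abs(dd), 0.0, w, w, sign=1 if dd > 0 else -1)
        from seedperturb.peaks import PeakFitResult

        return PeakFitResult(model=model, dose_difference=dd, fwhm=w, sse=0.0, n_points=51, converged=True)

    def test_two_point_stats(self):
        s = summarize_cluster([self._fit(-10.0), self._fit(-12.0)])
        assert s.mean_dd == pytest.approx(-11.0)
        assert s.sd_dd == pytest.approx(math.sqrt(2.0))

    def test_identical_fits_zero_sd(self):
        s = summarize_cluster([self._fit(-8.0, 0.7)] * 3)
        assert s.sd_dd == pytest.approx(0.0, abs=1e-12)
        assert s.sd_fwhm == pytest.approx(0.0, abs=1e-12)

    def test_fewer_than_two_errors(self):
        with pytest.raises(FitError, match=">=2"):
            summarize_cluster([self._fit(5.0)])

    def test_cluster_recovery_mean_within_ci(self):
        # 25 noisy fits with a common injected height: the cluster mean must
        # land inside a 4-sigma CI of the truth
        truth = PeakModel(f0=0.0, m=0.5, h_g=9.0, h_l=9.0, w_g=1.4, w_l=1.0, mu=0.0, sign=1)
        x = np.arange(-60, 61) * 0.1
        clean = evaluate_model(truth, x)
        fits = []
        for s in range(25):
            rng = np.random.default_rng(3000 + s)
            prof = PerturbationProfile(x, clean + 1.5 * rng.standard_normal(x.size), 0.1)
            mu0, sign = locate_peak(prof, 2.5)
            fits.append(fit_peak(prof, mu0, sign, bounds=PROTOCOL_BOUNDS, seed=s))
        summary = summarize_cluster(fits)
        se = summary.sd_dd / math.sqrt(len(fits))
        assert abs(summary.mean_dd - 9.0) < 4 * se + 0.5


class TestResultsFrame:
    def test_schema(self):
        truth = PeakModel(f0=0.0, m=0.4, h_g=8.0, h_l=8.0, w_g=1.6, w_l=0.9, mu=0.0, sign=1)
        prof = profile_from_model(truth)
        fit = fit_peak(prof, 0.0, 1, seed=0)
        frame = results_frame([fit], ["seed0"])
        assert list(frame.columns) == [
            "label", "sign", "dose_difference_percent", "fwhm_mm", "M",
            "A_G", "A_L", "W_G_mm", "W_L_mm", "mu_mm", "F0", "sse",
            "n_points", "converged",
        ]
        assert frame.loc[0, "label"] == "seed0"


class TestModelValidation:
    def test_m_out_of_range(self):
        with pytest.raises(FitError, match="m must"):
            PeakModel(f0=0, m=1.5, h_g=1, h_l=1, w_g=1, w_l=1, mu=0, sign=1)

    def test_negative_height(self):
        with pytest.raises(FitError):
            PeakModel(f0=0, m=0.5, h_g=-1, h_l=1, w_g=1, w_l=1, mu=0, sign=1)

    def test_bad_sign(self):
        with pytest.raises(FitError, match="sign"):
            PeakModel(f0=0, m=0.5, h_g=1, h_l=1, w_g=1, w_l=1, mu=0, sign=0)
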