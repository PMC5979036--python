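"""Gamma-variate + sigmoid mixture model and its voxel-wise fit."""

import numpy as np
import pytest
from scipy.integrate import quad

from dscmri import (
    DeltaR2Series,
    FitOptions,
    GammaVariateParams,
    NoBolusError,
    SigmoidParams,
    eval_gamma_variate,
    eval_mixture,
    eval_sigmoid,
    fit_bolus_mixture,
    initial_guess,
)


def series_from_curve(values, acq):
    return DeltaR2Series(values=np.asarray(values, float), si0=500.0, acq=acq)


class TestGammaVariate:
    def test_zero_at_and_before_onset(self):
        p = GammaVariateParams(t0=10.0, k=1.0, alpha=2.0, beta=5.0)
        assert eval_gamma_variate(p, [0.0, 5.0, 10.0]).tolist() == [0.0, 0.0, 0.0]

    def test_peak_at_t0_plus_alpha_beta(self):
        p = GammaVariateParams(t0=10.0, k=1.0, alpha=2.0, beta=5.0)
        t = np.linspace(10.0, 80.0, 70001)
        assert t[np.argmax(eval_gamma_variate(p, t))] == pytest.approx(20.0, abs=2e-3)

    def test_integral_matches_gamma_function(self):
        """Quadrature of k t^alpha e^(-t/beta) equals k beta^(a+1) Γ(a+1)."""
        p = GammaVariateParams(t0=0.0, k=1.0, alpha=1.0, beta=10.0)
        val, err = quad(lambda t: eval_gamma_variate(p, np.array([t]))[0], 0, np.inf)
        assert val == pytest.approx(100.0, rel=1e-8)

    def test_nonnegative_everywhere(self):
        p = GammaVariateParams(t0=3.0, k=0.5, alpha=0.7, beta=2.0)
        t = np.linspace(-10, 100, 500)
        assert np.all(eval_gamma_variate(p, t) >= 0)

    def test_invalid_params_rejected(self):
        from dscmri import InputError

        with pytest.raises(InputError):
            GammaVariateParams(t0=0.0, k=-1.0, alpha=1.0, beta=1.0)
        with pytest.raises(InputError):
            GammaVariateParams(t0=0.0, k=1.0, alpha=0.0, beta=1.0)


class TestSigmoid:
    def test_half_amplitude_at_centre(self):
        p = SigmoidParams(s=4.0, tc=20.0, r=0.5)
        assert eval_sigmoid(p, 20.0) == pytest.approx(2.0)

    def test_asymptotes(self):
        p = SigmoidParams(s=4.0, tc=20.0, r=0.5)
        assert eval_sigmoid(p, -1e6) == pytest.approx(0.0, abs=1e-12)
        assert eval_sigmoid(p, 1e6) == pytest.approx(4.0, rel=1e-12)

    def test_logistic_quantile(self):
        """s/(1+exp(-r(t-tc))) = 3 at t = tc + 2 ln 3 for s=4, r=1/2."""
        p = SigmoidParams(s=4.0, tc=20.0, r=0.5)
        assert eval_sigmoid(p, 20.0 + 2.0 * np.log(3.0)) == pytest.approx(3.0)

    def test_monotone_non_decreasing(self):
        p = SigmoidParams(s=2.0, tc=5.0, r=0.1)
        t = np.linspace(-50, 80, 400)
        assert np.all(np.diff(eval_sigmoid(p, t)) >= 0)


class TestInitialGuess:
    def test_noiseless_mixture_guess_converges(self, acq_default):
        gamma = GammaVariateParams(t0=242.0, k=0.03, alpha=3.0, beta=8.0)
        sig = SigmoidParams(s=3.0, tc=292.0, r=0.3)
        dr2 = series_from_curve(
            eval_mixture(gamma, sig, acq_default.frame_times), acq_default
        )
        g0, s0 = initial_guess(dr2)
        assert g0.t0 >= 0 and g0.alpha > 0 and g0.beta > 0 and s0.r > 0
        fit = fit_bolus_mixture(dr2)
        assert fit.valid and fit.rss < 1e-12

    def test_all_zero_series_has_no_bolus(self, acq_short):
        dr2 = series_from_curve(np.zeros(acq_short.n_frames), acq_short)
        with pytest.raises(NoBolusError):
            initial_guess(dr2)

    def test_baseline_peak_has_no_bolus(self, acq_short):
        v = np.zeros(acq_short.n_frames)
        v[10] = 5.0  # inside the baseline window
        with pytest.raises(NoBolusError):
            initial_guess(series_from_curve(v, acq_short))

    def test_subthreshold_peak_rejected_by_noise_floor(self, acq_short):
        rng = np.random.default_rng(5)
        v = rng.normal(0.0, 1.0, acq_short.n_frames)
        v[50] = 2.0  # below 3 sd of baseline noise
        with pytest.raises(NoBolusError):
            initial_guess(series_from_curve(v, acq_short), noise_floor=3.0)


class TestFitBolusMixture:
    TRUTH_GAMMA = GammaVariateParams(
        t0=242.0, k=20.0 * np.exp(-3.0 * (np.log(24.0) - 1.0)), alpha=3.0, beta=8.0
    )
    TRUTH_SIG = SigmoidParams(s=3.0, tc=292.0, r=0.3)

    def fit_noiseless(self, acq):
        curve = eval_mixture(self.TRUTH_GAMMA, self.TRUTH_SIG, acq.frame_times)
        dr2 = series_from_curve(curve, acq)
        return fit_bolus_mixture(dr2), dr2

    def test_noiseless_parameter_recovery_within_1pct(self, acq_default):
        fit, _ = self.fit_noiseless(acq_default)
        assert fit.valid
        for name in ("t0", "k", "alpha", "beta"):
            got, want = getattr(fit.gamma, name), getattr(self.TRUTH_GAMMA, name)
            assert got == pytest.approx(want, rel=0.01), name
        for name in ("s", "tc", "r"):
            got, want = getattr(fit.sigmoid, name), getattr(self.TRUTH_SIG, name)
            assert got == pytest.approx(want, rel=0.01), name

    def test_noiseless_rss_at_machine_precision(self, acq_default):
        fit, _ = self.fit_noiseless(acq_default)
        assert fit.rss < 1e-12

    def test_pure_gamma_recirculation_stays_near_zero(self, acq_default):
        """With no recirculation the fitted plateau is ≤ 2% of the peak."""
        curve = eval_gamma_variate(self.TRUTH_GAMMA, acq_default.frame_times)
        fit = fit_bolus_mixture(series_from_curve(curve, acq_default))
        assert fit.valid
        assert fit.sigmoid.s <= 0.02 * 20.0

    def test_fit_rss_not_worse_than_initial_guess(self, acq_default, rng):
        curve = eval_mixture(self.TRUTH_GAMMA, self.TRUTH_SIG,
                             acq_default.frame_times)
        noisy = curve + rng.normal(0, 1.0, curve.size)
        dr2 = series_from_curve(noisy, acq_default)
        g0, s0 = initial_guess(dr2)
        rss0 = float(np.sum((eval_mixture(g0, s0, acq_default.frame_times) - noisy) ** 2))
        fit = fit_bolus_mixture(dr2)
        assert fit.rss <= rss0 + 1e-9

    def test_peak_delay_recovery_under_noise(self, acq_default, rng):
        """Median |relative error| of the peak delay alpha*beta stays below
        5% with Gaussian noise of 5% of the peak on 100 voxels."""
        curve = eval_mixture(self.TRUTH_GAMMA, self.TRUTH_SIG,
                             acq_default.frame_times)
        sd = 0.05 * 20.0
        errs = []
        for _ in range(100):
            noisy = curve + rng.normal(0, sd, curve.size)
            fit = fit_bolus_mixture(series_from_curve(noisy, acq_default))
            if not fit.valid:
                continue
            delay = fit.gamma.alpha * fit.gamma.beta
            errs.append(abs(delay - 24.0) / 24.0)
        assert len(errs) >= 90
        assert np.median(errs) < 0.05

    def test_time_shift_equivariance(self, acq_default):
        """Shifting the series by Δ frames shifts t0 and tc by Δ·TR and
        leaves the shape parameters unchanged."""
        delta = 7
        fits = []
        for shift in (0, delta):
            g = GammaVariateParams(
                t0=self.TRUTH_GAMMA.t0 + shift * acq_default.tr,
                k=self.TRUTH_GAMMA.k, alpha=self.TRUTH_GAMMA.alpha,
                beta=self.TRUTH_GAMMA.beta,
            )
            s = SigmoidParams(
                s=self.TRUTH_SIG.s, tc=self.TRUTH_SIG.tc + shift * acq_default.tr,
                r=self.TRUTH_SIG.r,
            )
            curve = eval_mixture(g, s, acq_default.frame_times)
            fits.append(fit_bolus_mixture(series_from_curve(curve, acq_default)))
        f0, f1 = fits
        assert f1.gamma.t0 - f0.gamma.t0 == pytest.approx(delta * acq_default.tr,
                                                          abs=1e-3)
        assert f1.sigmoid.tc - f0.sigmoid.tc == pytest.approx(delta * acq_default.tr,
                                                              abs=1e-2)
        for name in ("k", "alpha", "beta"):
            assert getattr(f1.gamma, name) == pytest.approx(
                getattr(f0.gamma, name), rel=1e-4
            )

    def test_graceful_degradation_with_noise(self, acq_default):
        """Median parameter error does not decrease as noise grows."""
        curve = eval_mixture(self.TRUTH_GAMMA, self.TRUTH_SIG,
                             acq_default.frame_times)
        med_errs = []
        for i, frac in enumerate([0.0, 0.01, 0.05, 0.10]):
            rng = np.random.default_rng(100 + i)
            errs = []
            for _ in range(20):
                noisy = curve + rng.normal(0, frac * 20.0, curve.size)
                try:
                    fit = fit_bolus_mixture(series_from_curve(noisy, acq_default))
                except NoBolusError:
                    continue
                delay = fit.gamma.alpha * fit.gamma.beta
                errs.append(abs(delay - 24.0) / 24.0)
            med_errs.append(np.median(errs))
        assert all(
            b >= a - 1e-12 for a, b in zip(med_errs, med_errs[1:])
        ), med_errs

    def test_nobolus_propagates(self, acq_short):
        dr2 = series_from_curve(np.zeros(acq_short.n_frames), acq_short)
        with pytest.raises(NoBolusError):
            fit_bolus_mixture(dr2)

    def test_restart_path_is_seeded_and_no_worse(self, acq_default):
        curve = eval_mixture(self.TRUTH_GAMMA, self.TRUTH_SIG,
                             acq_default.frame_times)
        noisy = curve + np.random.default_rng(3).normal(0, 1.0, curve.size)
        dr2 = series_from_curve(noisy, acq_default)
        plain = fit_bolus_mixture(dr2)
        opts = FitOptions(n_restarts=2, restart_seed=9)
        again = fit_bolus_mixture(dr2, opts)
        third = fit_bolus_mixture(dr2, opts)
        assert again.rss <= plain.rss + 1e-9
        assert again.rss == third.rss  # deterministic given the seed
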