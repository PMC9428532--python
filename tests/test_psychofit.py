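import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy.optimize import brentq

from revspeech import psychofit as pf


class TestPsychometricAnchors:
    def test_midpoint_identity(self):
        # psi(m) = gamma + (1 - gamma - lambda)/2
        assert pf.psychometric(-4.0, m=-4.0, gamma=0.1, lam=0.02, w=8.0) \
            == pytest.approx(0.1 + (1 - 0.1 - 0.02) / 2, abs=1e-15)

    def test_midpoint_054(self):
        assert pf.psychometric(0.0, m=0.0, w=10.0, gamma=0.1, lam=0.02) \
            == pytest.approx(0.54, abs=1e-12)

    def test_width_upper_anchor(self):
        # psi(m + w/2) at 95 % of the range
        val = pf.psychometric(1.0 + 4.0, m=1.0, w=8.0, gamma=0.1, lam=0.0)
        assert val == pytest.approx(0.1 + 0.9 * 0.95, abs=1e-12)

    def test_width_lower_anchor(self):
        val = pf.psychometric(1.0 - 4.0, m=1.0, w=8.0, gamma=0.1, lam=0.0)
        assert val == pytest.approx(0.1 + 0.9 * 0.05, abs=1e-12)

    @given(m=hst.floats(-20, 5), w=hst.floats(1, 30),
           gamma=hst.floats(0, 0.5), lam=hst.floats(0, 0.05))
    @settings(max_examples=50, deadline=None)
    def test_anchor_identities_hold_everywhere(self, m, w, gamma, lam):
        span = 1 - gamma - lam
        assert pf.psychometric(m, m, w, gamma, lam) == pytest.approx(
            gamma + span / 2, abs=1e-12)
        assert pf.psychometric(m + w / 2, m, w, gamma, lam) == pytest.approx(
            gamma + span * 0.95, abs=1e-12)
        assert pf.psychometric(m - w / 2, m, w, gamma, lam) == pytest.approx(
            gamma + span * 0.05, abs=1e-12)

    @given(m=hst.floats(-10, 0), w=hst.floats(2, 20))
    @settings(max_examples=30, deadline=None)
    def test_strictly_increasing(self, m, w):
        x = np.linspace(m - w, m + w, 101)
        y = pf.psychometric(x, m, w)
        assert np.all(np.diff(y) > 0)


class TestFit:
    @staticmethod
    def _simulate(m, w, lam, snrs, words_per_snr, rng):
        p = pf.psychometric(np.asarray(snrs, float), m, w, 0.1, lam)
        k = rng.binomial(words_per_snr, p)
        return (np.asarray(snrs, float),
                np.full(len(snrs), words_per_snr), k)

    def test_dense_data_recovery(self):
        rng = np.random.default_rng(0)
        snrs = np.linspace(-16, 0, 9)
        s, n, k = self._simulate(-8.0, 9.0, 0.01, snrs, 5000, rng)
        fit = pf.fit_psychometric(s, n, k)
        assert fit.converged
        assert fit.m == pytest.approx(-8.0, abs=0.2)

    def test_floor_only_flagged(self):
        snrs = np.array([-16.0, -12.0, -8.0, -4.0, 0.0])
        n = np.full(5, 50)
        k = np.full(5, 5)  # constant 10 % = chance
        fit = pf.fit_psychometric(snrs, n, k)
        assert not fit.converged

    def test_too_few_snrs_rejected(self):
        with pytest.raises(ValueError):
            pf.fit_psychometric([0.0, 1.0], [50, 50], [10, 40])

    def test_translation_invariance(self):
        rng = np.random.default_rng(7)
        snrs = np.array([-16.0, -12.0, -8.0, -4.0, 0.0])
        s, n, k = self._simulate(-8.0, 9.0, 0.0, snrs, 50, rng)
        f0 = pf.fit_psychometric(s, n, k)
        f1 = pf.fit_psychometric(s + 6.0, n, k)
        assert f1.m == pytest.approx(f0.m + 6.0, abs=1e-3)
        assert f1.w == pytest.approx(f0.w, abs=1e-3)

    def test_study_density_recovery(self):
        # 50 words x 5 SNRs; median |m_hat - m| < 1 dB over replicates
        rng = np.random.default_rng(1)
        snrs = np.array([-16.0, -12.0, -8.0, -4.0, 0.0])
        errs_m, errs_w = [], []
        for _ in range(60):
            m_true = rng.uniform(-10, -6)
            w_true = rng.uniform(7, 11)
            s, n, k = self._simulate(m_true, w_true, 0.01, snrs, 50, rng)
            fit = pf.fit_psychometric(s, n, k)
            errs_m.append(abs(fit.m - m_true))
            errs_w.append(abs(fit.w - w_true) / w_true)
        assert np.median(errs_m) < 1.0
        assert np.median(errs_w) < 0.25

    def test_gaussian_variant_close_to_logistic(self):
        rng = np.random.default_rng(5)
        snrs = np.array([-16.0, -12.0, -8.0, -4.0, 0.0])
        s, n, k = self._simulate(-8.0, 9.0, 0.0, snrs, 200, rng)
        f_log = pf.fit_psychometric(s, n, k)
        f_gau = pf.fit_gaussian_psychometric(s, n, k)
        assert f_gau.m == pytest.approx(f_log.m, abs=1.0)


class TestRau:
    def test_endpoints_and_midpoint(self):
        assert pf.rau(0.0) == pytest.approx(-23.0, abs=1e-12)
        assert pf.rau(1.0) == pytest.approx(123.0, abs=1e-12)
        assert pf.rau(0.5) == pytest.approx(50.0, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pf.rau(1.2)
        with pytest.raises(ValueError):
            pf.rau(-0.1)

    @given(hst.floats(0.0, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_inverse_roundtrip(self, p):
        assert pf.inverse_rau(pf.rau(p)) == pytest.approx(p, abs=1e-10)

    def test_strictly_increasing(self):
        p = np.linspace(0, 1, 1001)
        assert np.all(np.diff(pf.rau(p)) > 0)

    def test_counts_form_matches_continuous_for_large_n(self):
        # integer form approaches the continuous transform
        assert pf.rau_counts(500, 1000) == pytest.approx(pf.rau(0.5), abs=0.5)

    def test_counts_bounds(self):
        with pytest.raises(ValueError):
            pf.rau_counts(6, 5)


class TestMeanGroupCurve:
    def test_identical_fits(self):
        f = pf.PsychometricFit(m=-5.0, w=8.0, lam=0.02)
        mean = pf.mean_group_curve([f, f, f])
        assert mean.m == f.m and mean.w == f.w and mean.lam == f.lam

    def test_parameter_means(self):
        fits = [pf.PsychometricFit(m=-6.0, w=8.0),
                pf.PsychometricFit(m=-2.0, w=10.0)]
        mean = pf.mean_group_curve(fits)
        assert mean.m == -4.0 and mean.w == 9.0

    def test_midpoint_identity_of_mean_curve(self):
        fits = [pf.PsychometricFit(m=-6.0, w=8.0, lam=0.04),
                pf.PsychometricFit(m=-2.0, w=10.0, lam=0.0)]
        mean = pf.mean_group_curve(fits)
        assert mean(mean.m) == pytest.approx(
            mean.gamma + (1 - mean.gamma - mean.lam) / 2, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pf.mean_group_curve([])


class TestOptimalSnr:
    def test_single_winner(self):
        fits = [pf.PsychometricFit(m=-8.0, w=6.0) for _ in range(5)]
        # at -8 all scores are 0.55 (inside); at +20 all at ceiling
        assert pf.optimal_snr(fits, [-8.0, 20.0]) == -8.0

    def test_tie_breaks_low(self):
        fits = [pf.PsychometricFit(m=-8.0, w=6.0)]
        assert pf.optimal_snr(fits, [-8.0, -7.0]) == -8.0

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            pf.optimal_snr([], [])

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        fits = [pf.PsychometricFit(m=rng.uniform(-12, -4),
                                   w=rng.uniform(5, 15),
                                   lam=rng.uniform(0, 0.05))
                for _ in range(40)]
        grid = np.arange(-16.0, 1.0, 2.0)
        # brute force oracle
        best, best_count = None, -1
        for s in grid:
            c = sum(1 for f in fits if 0.15 < f(s) < 0.95)
            if c > best_count:
                best, best_count = s, c
        assert pf.optimal_snr(fits, grid) == best


class TestDipBenefit:
    def test_identical_fits_zero(self):
        f = pf.PsychometricFit(m=-8.0, w=9.0)
        assert pf.dip_benefit(f, f, -8.0) == 0.0

    def test_ceiling_saturation(self):
        a = pf.PsychometricFit(m=-8.0, w=6.0)
        b = pf.PsychometricFit(m=-6.0, w=6.0)
        assert abs(pf.dip_benefit(a, b, 30.0)) < 0.5

    def test_shifted_curve_positive_benefit(self):
        stat = pf.PsychometricFit(m=-6.0, w=9.0)
        mod = pf.PsychometricFit(m=-10.0, w=9.0)
        for s in (-10.0, -8.0, -6.0):
            assert pf.dip_benefit(mod, stat, s) > 0


class TestSrt:
    def test_symmetric_sigmoid(self):
        f = pf.PsychometricFit(m=-5.0, w=8.0, gamma=0.0, lam=0.0)
        assert pf.srt(f) == pytest.approx(-5.0, abs=1e-12)

    def test_guess_rate_shifts_srt_down(self):
        f = pf.PsychometricFit(m=-5.0, w=8.0, gamma=0.1, lam=0.0)
        assert pf.srt(f) < -5.0

    def test_matches_root_finding(self):
        f = pf.PsychometricFit(m=-5.0, w=8.0, gamma=0.1, lam=0.03)
        root = brentq(lambda x: f(x) - 0.5, -40, 30, xtol=1e-12)
        assert pf.srt(f) == pytest.approx(root, abs=1e-6)

    def test_unattainable_criterion_rejected(self):
        f = pf.PsychometricFit(m=-5.0, w=8.0, gamma=0.6)
        with pytest.raises(ValueError):
            pf.srt(f)

    def test_nan_free(self):
        f = pf.PsychometricFit(m=0.0, w=5.0, gamma=0.1, lam=0.05)
        assert math.isfinite(pf.srt(f))
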