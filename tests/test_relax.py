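"""Exponential relaxation fitting, Monte Carlo errors, R1rho->R2
conversion, NOE and the helical-baseline dynamics flags."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spinflex import relax
from spinflex import synthetic as syn
from spinflex.types import Peak, RateResult, RelaxSeries, SpinLockSettings

DELAYS = np.array([0.0, 0.4, 1.4, 2.4, 3.6])


def make_series(rate, i0=100.0, delays=DELAYS, err=1.0, residue=1):
    inten = i0 * np.exp(-rate * delays)
    return RelaxSeries(residue, "R1", delays, inten,
                       np.full(len(delays), err))


class TestFitExponential:
    def test_constant_series_gives_zero_rate(self):
        s = RelaxSeries(1, "R1", DELAYS, np.full(5, 100.0), np.full(5, 2.0))
        fit = relax.fit_exponential(s)
        assert fit.rate == pytest.approx(0.0, abs=1e-8)
        assert fit.amplitude == pytest.approx(100.0, rel=1e-8)

    def test_noiseless_model_recovered_exactly(self):
        fit = relax.fit_exponential(make_series(2.0, i0=50.0))
        assert fit.rate == pytest.approx(2.0, rel=1e-6)
        assert fit.amplitude == pytest.approx(50.0, rel=1e-6)

    def test_two_point_closed_form(self):
        # R = ln(I1/I2) / (t2 - t1)
        s = RelaxSeries(1, "R1", [0.0, 1.0], [80.0, 80.0 / math.e],
                        [1.0, 1.0])
        fit = relax.fit_exponential(s)
        assert fit.rate == pytest.approx(1.0, rel=1e-8)

    def test_unfittable_series_flagged_not_nan_crash(self):
        s = RelaxSeries(1, "R1", [0.5], [42.0], [1.0])
        fit = relax.fit_exponential(s)
        assert not fit.converged
        assert "unfittable" in fit.message

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(rate=st.floats(0.1, 20.0), i0=st.floats(1.0, 1e6))
    def test_recovery_over_full_rate_range(self, rate, i0):
        fit = relax.fit_exponential(make_series(rate, i0=i0, err=i0 * 0.02))
        assert fit.rate == pytest.approx(rate, rel=1e-6)
        assert fit.amplitude == pytest.approx(i0, rel=1e-6)


class TestMonteCarloError:
    def test_vanishing_noise_gives_vanishing_errors(self):
        s = make_series(1.5, err=1e-9)
        fit = relax.fit_exponential(s)
        rate_err, amp_err = relax.monte_carlo_error(s, fit, n_mc=50, seed=0)
        assert rate_err < 1e-9
        assert amp_err < 1e-6

    def test_same_seed_reproduces_errors_exactly(self):
        s = make_series(1.5, err=2.0)
        fit = relax.fit_exponential(s)
        e1 = relax.monte_carlo_error(s, fit, n_mc=100, seed=42)
        e2 = relax.monte_carlo_error(s, fit, n_mc=100, seed=42)
        assert e1 == e2

    def test_error_scales_linearly_with_noise(self):
        fits = []
        for err in (1.0, 2.0):
            s = make_series(1.5, err=err)
            fit = relax.fit_exponential(s)
            fits.append(relax.monte_carlo_error(s, fit, n_mc=800, seed=3)[0])
        assert fits[1] / fits[0] == pytest.approx(2.0, rel=0.15)

    def test_too_few_replicates_rejected(self):
        s = make_series(1.5)
        with pytest.raises(ValueError):
            relax.monte_carlo_error(s, relax.fit_exponential(s), n_mc=1)


class TestR1rhoToR2:
    def _rate(self, value, err=0.1, residue=1, exp="R1"):
        return RateResult(residue, exp, value, 100.0, rate_error=err)

    def test_on_resonance_r2_equals_r1rho(self):
        sl = SpinLockSettings(omega_sl=1923.0, offset=0.0)
        r2, _ = relax.r1rho_to_r2(self._rate(12.0, exp="R1rho"),
                                  self._rate(1.0), sl)
        assert r2 == pytest.approx(12.0)

    def test_forty_five_degree_tilt(self):
        # theta = 45 deg: R2 = 2*R1rho - R1 = 2*10 - 1 = 19
        sl = SpinLockSettings(omega_sl=1923.0, offset=1923.0)
        r2, _ = relax.r1rho_to_r2(self._rate(10.0, exp="R1rho"),
                                  self._rate(1.0), sl)
        assert r2 == pytest.approx(19.0)

    def test_continuous_in_offset_near_resonance(self):
        near = SpinLockSettings(omega_sl=1923.0, offset=1.0)
        r2_near, _ = relax.r1rho_to_r2(self._rate(10.0, exp="R1rho"),
                                       self._rate(1.0), near)
        assert r2_near == pytest.approx(10.0, abs=1e-4)

    def test_mismatched_residues_rejected(self):
        sl = SpinLockSettings(omega_sl=1923.0)
        with pytest.raises(ValueError):
            relax.r1rho_to_r2(self._rate(10.0, residue=1),
                              self._rate(1.0, residue=2), sl)

    def test_error_propagation_matches_monte_carlo(self):
        sl = SpinLockSettings(omega_sl=1923.0, offset=1000.0)
        r1rho = self._rate(10.0, err=0.5, exp="R1rho")
        r1 = self._rate(1.2, err=0.05)
        _, analytic = relax.r1rho_to_r2(r1rho, r1, sl)
        rng = np.random.default_rng(0)
        theta = math.radians(sl.theta_deg)
        draws = (rng.normal(10.0, 0.5, 40000) / math.sin(theta) ** 2
                 - rng.normal(1.2, 0.05, 40000) / math.tan(theta) ** 2)
        assert analytic == pytest.approx(np.std(draws, ddof=1), rel=0.05)


class TestNOE:
    def _peak(self, height, err, residue=68):
        return Peak(residue, "N-H", 8.2, 119.0, height, err)

    def test_equal_heights_give_unity_with_quadrature_error(self):
        r = relax.compute_noe(self._peak(100, 2), self._peak(100, 2))
        assert r.noe == pytest.approx(1.0)
        assert r.noe_error == pytest.approx(math.sqrt(2) * 0.02, rel=1e-6)

    def test_depressed_noe_magnitude(self):
        # mimics the scale of a mobile amide (0.43) without asserting it
        r = relax.compute_noe(self._peak(43, 2), self._peak(100, 2))
        assert r.noe == pytest.approx(0.43)
        assert r.noe_error == pytest.approx(
            0.43 * math.sqrt((2 / 43) ** 2 + (2 / 100) ** 2), rel=1e-9)
        assert r.noe_error == pytest.approx(0.022, abs=5e-4)

    def test_zero_saturated_height_allowed(self):
        r = relax.compute_noe(self._peak(0, 2), self._peak(100, 2))
        assert r.noe == 0.0
        assert r.noe_error == pytest.approx(0.02)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            relax.compute_noe(self._peak(50, 2), self._peak(0, 2))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(height=st.floats(1.0, 1e6), err_frac=st.floats(0.001, 0.2))
    def test_self_ratio_is_one(self, height, err_frac):
        p = self._peak(height, err_frac * height)
        assert relax.compute_noe(p, p).noe == pytest.approx(1.0)


class TestBaselineFlags:
    HELIX = ((10, 30),)

    def _profiles(self, loops=(), r1_shift=0.0):
        rng = np.random.default_rng(1)
        r1 = {r: 1.2 + 0.02 * rng.standard_normal() + r1_shift
              for r in range(10, 31)}
        noe = {r: 0.80 + 0.01 * rng.standard_normal() for r in range(10, 31)}
        sd_r1 = np.std(list(r1.values()), ddof=1)
        sd_noe = np.std(list(noe.values()), ddof=1)
        for r in loops:
            r1[r] = np.mean(list(r1.values())) + 5 * sd_r1 + r1_shift
            noe[r] = np.mean(list(noe.values())) - 5 * sd_noe
        return r1, noe

    def test_identical_profiles_raise_no_flags(self):
        r1 = {r: 1.2 for r in range(10, 31)}
        noe = {r: 0.8 for r in range(10, 31)}
        out = relax.baseline_and_flags(r1, noe, self.HELIX)
        assert out["flagged"] == []

    def test_constructed_outliers_are_exactly_flagged(self):
        loops = (66, 67, 68, 69, 70)
        r1, noe = self._profiles(loops=loops)
        out = relax.baseline_and_flags(r1, noe, self.HELIX)
        assert sorted(out["flagged"]) == sorted(loops)

    def test_flags_invariant_under_constant_r1_shift(self):
        loops = (66, 68)
        r1, noe = self._profiles(loops=loops)
        base = relax.baseline_and_flags(r1, noe, self.HELIX)["flagged"]
        shifted = {r: v + 7.5 for r, v in r1.items()}
        assert relax.baseline_and_flags(shifted, noe, self.HELIX)["flagged"] == base

    def test_missing_annotation_rejected(self):
        with pytest.raises(ValueError):
            relax.baseline_and_flags({1: 1.0}, {1: 0.8}, ())

    def test_too_few_helical_residues_rejected(self):
        r1 = {r: 1.2 for r in range(10, 13)}
        noe = {r: 0.8 for r in range(10, 13)}
        with pytest.raises(ValueError, match=">= 5"):
            relax.baseline_and_flags(r1, noe, ((10, 12),))
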