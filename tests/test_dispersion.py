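"""CPMG dispersion: R2,eff conversion, Rex, two-state MQ/SQ models
against independent integrators, and global kex fitting."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from spinflex import dispersion as dsp
from spinflex import synthetic as syn
from spinflex.types import CPMGSettings, DispersionCurve

NU_SIMPLE = np.array([50.0, 100.0, 200.0, 400.0, 600.0, 800.0, 1000.0])


def mq_settings(field=800.0, T=0.02, nu=NU_SIMPLE):
    return CPMGSettings(T_relax=T, nu_cpmg=np.asarray(nu, float),
                        field_1H=field, coherence="MQ_13C")


def sq_settings(field=800.0, T=0.02, nu=NU_SIMPLE):
    return CPMGSettings(T_relax=T, nu_cpmg=np.asarray(nu, float),
                        field_1H=field, coherence="SQ_1H")


def oracle_r2eff(nu_val, T, kex, pb, dw_ref, dw_stat, method="expm"):
    """Independent propagation of the two-state CPMG evolution.

    Uses scipy's Pade matrix exponential (or an ODE integrator) and an
    explicit per-element loop; detection and branch averaging follow
    the physics: major-state coherence from equilibrium start,
    averaged over the two starting branches.
    """
    k_ab, k_ba = pb * kex, (1 - pb) * kex
    n = int(round(nu_val * T))
    tau = T / (4 * n)
    lp = np.array([[-k_ab, k_ba], [k_ab, -k_ba + 1j * (dw_stat + dw_ref)]])
    lm = np.array([[-k_ab, k_ba], [k_ab, -k_ba + 1j * (dw_stat - dw_ref)]])

    if method == "expm":
        ev = lambda L, t: expm(L * t)
    else:  # adaptive ODE integration of dv/dt = L v
        def ev(L, t):
            cols = []
            for e in np.eye(2, dtype=complex):
                sol = solve_ivp(lambda _, v: L @ v, (0, t), e,
                                rtol=1e-10, atol=1e-12)
                cols.append(sol.y[:, -1])
            return np.array(cols).T

    sig = 0.0
    for first, second in ((lp, lm), (lm, lp)):
        u = np.eye(2, dtype=complex)
        for _ in range(n):
            u = ev(first, tau) @ ev(second, 2 * tau) @ ev(first, tau) @ u
        v = u @ np.array([1 - pb, pb])
        sig += 0.5 * abs(v[0]) / (1 - pb)
    return -math.log(sig) / T


class TestR2effConversion:
    def test_reference_intensities_give_zero_rate(self):
        s = mq_settings(nu=np.array([50.0, 100.0, 200.0, 200.0]))
        curve = dsp.r2eff_from_intensities(np.array([5.0, 5.0, 5.0, 5.0]),
                                           5.0, s)
        assert np.allclose(curve.r2eff, 0.0)

    def test_closed_form_log_ratio(self):
        s = mq_settings(nu=np.array([100.0, 200.0, 200.0]))
        i = 2.0 * np.exp(-0.3)
        curve = dsp.r2eff_from_intensities(np.array([i, i, i]), 2.0, s)
        assert curve.r2eff == pytest.approx(15.0)  # 0.3 / 0.020 s

    def test_duplicate_points_pooled_mean_and_sd(self):
        s = mq_settings(nu=np.array([100.0, 200.0, 200.0]))
        i0 = 2.0
        i_200 = i0 * np.exp(-np.array([14.9, 15.1]) * 0.02)
        ints = np.array([i0 * np.exp(-10.0 * 0.02), i_200[0], i_200[1]])
        curve = dsp.r2eff_from_intensities(ints, i0, s)
        pooled = curve.r2eff[np.isclose(curve.nu_unique, 200.0)][0]
        err = curve.r2eff_error[np.isclose(curve.nu_unique, 200.0)][0]
        assert pooled == pytest.approx(15.0)
        assert err == pytest.approx(np.std([14.9, 15.1], ddof=1))

    def test_nonpositive_intensities_dropped_with_warning(self):
        s = mq_settings(nu=np.array([100.0, 200.0, 200.0, 400.0]))
        with pytest.warns(UserWarning, match="broadened"):
            curve = dsp.r2eff_from_intensities(
                np.array([1.0, 0.9, 0.91, -0.1]), 2.0, s)
        assert len(curve.nu_unique) == 2

    def test_non_integer_cycle_count_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            mq_settings(nu=np.array([77.0]))


class TestRexEstimate:
    def _curve(self, r2eff, nu=np.array([50.0, 200.0, 1000.0])):
        s = mq_settings(nu=nu)
        return DispersionCurve("V64-Cg2", s, np.asarray(r2eff, float),
                               np.full(len(nu), 0.3), nu_unique=nu,
                               reference_intensity=2.0)

    def test_flat_curve_gives_zero(self):
        out = dsp.rex_estimate(self._curve([20.0, 20.0, 20.0]))
        assert out["rex"] == pytest.approx(0.0)

    def test_equals_direct_endpoint_subtraction(self):
        out = dsp.rex_estimate(self._curve([35.0, 28.0, 21.5]))
        assert out["rex"] == pytest.approx(35.0 - 21.5)
        assert out["rex_error"] == pytest.approx(math.hypot(0.3, 0.3))
        assert "underestimated" in out["caveat"]

    def test_antisymmetric_under_endpoint_swap(self):
        up = dsp.rex_estimate(self._curve([35.0, 28.0, 21.5]))["rex"]
        down = dsp.rex_estimate(self._curve([21.5, 28.0, 35.0]))["rex"]
        assert up == pytest.approx(-down)

    def test_intensity_mode_available_behind_flag(self):
        curve = self._curve([35.0, 28.0, 21.5])
        out = dsp.rex_estimate(curve, mode="intensity")
        i = 2.0 * np.exp(-np.array([35.0, 21.5]) * 0.02)
        assert out["rex"] == pytest.approx(i[0] - i[1])


class TestModelLimits:
    def test_no_minor_state_gives_flat_baseline(self):
        m = dsp.mq_model_r2eff(400.0, 1e-12, 1.5, 0.15, 20.0, mq_settings())
        assert np.allclose(m, 20.0, atol=1e-8)
        s = dsp.sq_model_r2eff(400.0, 1e-12, 0.5, 17.0, sq_settings())
        assert np.allclose(s, 17.0, atol=1e-8)

    def test_fast_exchange_collapse_to_baseline(self):
        m = dsp.mq_model_r2eff(1e6, 0.05, 1.5, 0.15, 20.0, mq_settings())
        assert np.abs(m - 20.0).max() < 0.25

    def test_invariant_under_simultaneous_shift_sign_flip(self):
        a = dsp.mq_model_r2eff(390.0, 0.05, 1.0, 0.1, 20.0, mq_settings())
        b = dsp.mq_model_r2eff(390.0, 0.05, -1.0, -0.1, 20.0, mq_settings())
        assert np.allclose(a, b, atol=1e-10)

    def test_sq_plateau_approaches_baseline_at_fast_pulsing(self):
        nu = np.array([5000.0, 10000.0])
        s = sq_settings(nu=nu)
        out = dsp.sq_model_r2eff(390.0, 0.05, 0.12, 20.0, s)
        assert np.abs(out - 20.0).max() < 0.01

    def test_rate_normalization_converges_as_period_grows(self):
        # the finite-cycle amplitude term scales as 1/T_relax: doubling
        # the constant-time period must shrink the rate difference
        nu = np.array([200.0, 400.0, 800.0])
        vals = [dsp.mq_model_r2eff(390.0, 0.05, 1.0, 0.02, 20.0,
                                   mq_settings(T=t, nu=nu)) for t in
                (0.02, 0.04, 0.08)]
        d1 = np.abs(vals[1] - vals[0]).max()
        d2 = np.abs(vals[2] - vals[1]).max()
        assert d2 < d1


@pytest.mark.parametrize("kex,pb,dwc,dwh", [
    (200.0, 0.03, 1.0, 0.05),
    (390.0, 0.05, 1.0, 0.02),
    (800.0, 0.10, 0.5, 0.10),
    (2000.0, 0.05, 0.3, 0.01),
])
class TestIntegrationOracle:
    def test_mq_matches_independent_integrator(self, kex, pb, dwc, dwh):
        s = mq_settings()
        model = dsp.mq_model_r2eff(kex, pb, dwc, dwh, 0.0, s)
        dw_c = dsp.dw_ppm_to_rad(dwc, s.field_1H, "C")
        dw_h = dsp.dw_ppm_to_rad(dwh, s.field_1H, "H")
        ref = [oracle_r2eff(v, s.T_relax, kex, pb, dw_c, dw_h)
               for v in s.nu_cpmg]
        assert np.abs(model - ref).max() < 0.05

    def test_sq_matches_independent_integrator(self, kex, pb, dwc, dwh):
        s = sq_settings()
        model = dsp.sq_model_r2eff(kex, pb, dwh + 0.1, 0.0, s)
        dw = dsp.dw_ppm_to_rad(dwh + 0.1, s.field_1H, "H")
        ref = [oracle_r2eff(v, s.T_relax, kex, pb, dw, 0.0)
               for v in s.nu_cpmg]
        assert np.abs(model - ref).max() < 0.05


def test_mq_matches_adaptive_ode_integration():
    s = mq_settings(nu=np.array([50.0, 400.0]))
    model = dsp.mq_model_r2eff(390.0, 0.05, 1.0, 0.02, 0.0, s)
    dw_c = dsp.dw_ppm_to_rad(1.0, 800.0, "C")
    dw_h = dsp.dw_ppm_to_rad(0.02, 800.0, "H")
    ref = [oracle_r2eff(v, 0.02, 390.0, 0.05, dw_c, dw_h, method="ode")
           for v in s.nu_cpmg]
    assert np.abs(model - ref).max() < 0.01


class TestClosedForms:
    def test_carver_richards_matches_propagation_at_many_cycles(self):
        # CR gives the asymptotic decay; compare where the cycle count
        # is large enough that initial-condition projection is small
        nu = np.array([300.0, 400.0, 500.0, 600.0, 800.0, 1000.0])
        for kex, pb, dw in [(1500.0, 0.02, 0.08), (2000.0, 0.02, 0.1),
                            (2500.0, 0.015, 0.12)]:
            s = sq_settings(nu=nu)
            cr = dsp.carver_richards_r2eff(kex, pb, dw, 20.0, s)
            nm = dsp.sq_model_r2eff(kex, pb, dw, 20.0, s)
            assert np.abs(cr - nm).max() < 0.05

    def test_fast_exchange_limit_agrees_with_luz_meiboom(self):
        s = sq_settings()
        dw_rad = dsp.dw_ppm_to_rad(0.1, 800.0, "H")
        kex = 12.0 * dw_rad  # kex >= 10 * dw puts us in fast exchange
        cr = dsp.carver_richards_r2eff(kex, 0.1, 0.1, 20.0, s)
        lm = dsp.luz_meiboom_r2eff(kex, 0.1, dw_rad, 20.0, s.nu_cpmg)
        assert np.abs((cr - lm) / lm).max() < 0.01

    def test_field_scaling_of_shift_differences(self):
        one = dsp.dw_ppm_to_rad(1.0, 600.0, "C")
        two = dsp.dw_ppm_to_rad(1.0, 1200.0, "C")
        assert two == pytest.approx(2.0 * one)


class TestGlobalFit:
    def _noiseless_curves(self, kex, pb, probes, fields=(800.0, 600.0)):
        curves = []
        for probe, (dwc, dwh) in probes.items():
            for f in fields:
                s = mq_settings(field=f, T=0.03,
                                nu=np.unique(syn.NU_CPMG_NA_MQ))
                model = dsp.mq_model_r2eff(kex, pb, dwc, dwh, 20.0, s)
                curves.append(DispersionCurve(
                    probe, s, model, np.full(len(model), 0.1),
                    nu_unique=s.nu_cpmg))
        return curves

    @pytest.mark.parametrize("kex,pb", [(200.0, 0.03), (400.0, 0.10),
                                        (800.0, 0.03)])
    def test_noiseless_recovery_across_regimes(self, kex, pb):
        curves = self._noiseless_curves(kex, pb,
                                        {"V64-Cg2": (1.0, 0.02)},
                                        fields=(800.0,))
        fit = dsp.fit_dispersion_global(curves)
        assert fit.params.kex == pytest.approx(kex, rel=5e-3)
        assert fit.params.p_b == pytest.approx(pb, rel=5e-3)

    def test_noiseless_two_probe_group_recovers_all_parameters(self):
        probes = {"V64-Cg2": (1.0, 0.02), "V59-Cg2": (0.3, 0.01)}
        fit = dsp.fit_dispersion_global(
            self._noiseless_curves(390.0, 0.05, probes))
        assert fit.params.kex == pytest.approx(390.0, rel=1e-3)
        assert fit.params.p_b == pytest.approx(0.05, rel=1e-3)
        for probe, (dwc, _) in probes.items():
            assert fit.params.dw_C[probe] == pytest.approx(dwc, rel=1e-2)

    def test_flat_curve_flagged_no_detectable_exchange(self):
        s = mq_settings(T=0.02)
        flat = np.full(len(s.nu_cpmg), 20.0)
        curve = DispersionCurve("X-1", s, flat, np.full(len(flat), 0.2),
                                nu_unique=s.nu_cpmg)
        fit = dsp.fit_dispersion_global([curve])
        assert fit.no_detectable_exchange

    def test_underdetermined_grouping_rejected(self):
        s = mq_settings(nu=np.array([100.0, 200.0]))
        curve = DispersionCurve("X-1", s, np.array([20.0, 19.0]),
                                np.array([0.2, 0.2]),
                                nu_unique=s.nu_cpmg)
        with pytest.raises(ValueError, match="nder-determined"):
            dsp.fit_dispersion_global([curve])
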