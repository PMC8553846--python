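"""CPMG relaxation-dispersion analysis under two-state chemical exchange.

Measured intensities at each CPMG pulsing rate nu are converted to
effective transverse rates, R2,eff(nu) = -(1/T_relax) * ln(I(nu)/I0),
with errors pooled from replicated nu points.  The exchange
contribution Rex is the difference in R2,eff between the lowest and
highest pulsing rates.

Model curves assume two-state exchange A <-> B with rate constants
k_AB = p_b*kex and k_BA = (1-p_b)*kex.  The 13C multiple-quantum (MQ)
model propagates the two-state MQ coherence numerically through each
CPMG element (tau - 180(13C) - tau)^n with 2x2 complex evolution
blocks: the MQ phase of the minor state combines the 1H and 13C shift
differences, and the 13C 180 pulse conjugates only the carbon part, so
the coherence alternates between the double- and zero-quantum branches.
The 1H single-quantum (SQ) model uses the same propagation with the
full phase conjugated by each pulse; the Carver-Richards closed form
and its Luz-Meiboom fast-exchange limit are kept as analytic
cross-checks.

Global fits share kex and p_b across curves (probes, fields and
coherence types) with per-probe shift differences and per-curve
exchange-free baselines, chi-square minimized from a multi-start grid.
"""

from __future__ import annotations

import math
import warnings
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .types import CPMGSettings, DispersionCurve, ExchangeParams, GroupFitResult

__all__ = [
    "GAMMA_RATIO",
    "dw_ppm_to_rad",
    "r2eff_from_intensities",
    "rex_estimate",
    "mq_model_r2eff",
    "sq_model_r2eff",
    "carver_richards_r2eff",
    "luz_meiboom_r2eff",
    "model_curve",
    "fit_dispersion_global",
]

#: |gamma_X / gamma_H| for the nuclei used here (CODATA-derived).
#: Truncated to three decimals these give the CSP weights 0.101 and 0.251.
GAMMA_RATIO = {"H": 1.0, "C": 0.251449530, "N": 0.101329118}

REX_CAVEAT = ("Rex from endpoint subtraction rather than a full dispersion "
              "fit; the error in Rex is likely underestimated.")


def dw_ppm_to_rad(dw_ppm: float, field_1H: float, nucleus: str) -> float:
    """Convert a shift difference in ppm to rad/s at a given field.

    ``field_1H`` is the 1H Larmor frequency in MHz; the nucleus'
    frequency is scaled by its gyromagnetic ratio relative to 1H, so
    doubling the field doubles the rad/s shift difference.
    """
    try:
        ratio = GAMMA_RATIO[nucleus]
    except KeyError:
        raise ValueError(f"unknown nucleus {nucleus!r}") from None
    return dw_ppm * 1e-6 * ratio * field_1H * 1e6 * 2.0 * math.pi


def r2eff_from_intensities(intensities: np.ndarray, reference: float,
                           settings: CPMGSettings, probe_id: str = ""
                           ) -> DispersionCurve:
    """Convert per-nu intensities to a replicate-pooled dispersion curve.

    R2,eff(nu) = -(1/T_relax) * ln(I(nu)/I0).  Replicated nu points are
    pooled: the value is their mean and the error the SD of the
    replicate R2,eff values, floored at the pooled (root-mean-square)
    replicate SD — a few-replicate SD below the pooled level is a
    downward fluctuation, not information, and would otherwise dominate
    weighted fits; non-replicated points get the pooled SD.  The
    pooled-variance estimator is unbiased where the median of 1-df pair
    SDs is not.  Non-positive intensities (exchange-broadened beyond
    detection) are dropped with a warning.
    """
    if not reference > 0:
        raise ValueError("reference intensity must be > 0")
    intensities = np.asarray(intensities, dtype=float)
    nu = settings.nu_cpmg
    if len(intensities) != len(nu):
        raise ValueError("one intensity per nu_CPMG value required")
    keep = intensities > 0
    if not np.all(keep):
        warnings.warn(
            f"probe {probe_id or '?'}: dropping {np.sum(~keep)} non-positive "
            f"intensity point(s) (exchange-broadened beyond detection)")
    nu, intensities = nu[keep], intensities[keep]
    r2 = -np.log(intensities / reference) / settings.T_relax

    nu_unique = np.unique(nu)
    values = np.empty_like(nu_unique)
    errors = np.full_like(nu_unique, np.nan)
    rep_sds = []
    for i, v in enumerate(nu_unique):
        sel = r2[np.isclose(nu, v)]
        values[i] = sel.mean()
        if len(sel) > 1:
            errors[i] = sel.std(ddof=1)
            rep_sds.append(errors[i])
    if not rep_sds:
        raise ValueError(
            "no replicated nu_CPMG points: R2,eff errors cannot be determined")
    fallback = float(np.sqrt(np.mean(np.square(rep_sds))))
    if fallback <= 0:
        # replicates agree exactly: noiseless (synthetic) data
        fallback = 1e-8
    errors = np.where(np.isfinite(errors), np.maximum(errors, fallback), fallback)
    return DispersionCurve(probe_id=probe_id, settings=settings, r2eff=values,
                           r2eff_error=errors, nu_unique=nu_unique,
                           reference_intensity=reference)


def rex_estimate(curve: DispersionCurve, mode: str = "r2eff") -> dict:
    """Exchange contribution from the dispersion-curve endpoints.

    ``mode="r2eff"`` (default): Rex = R2,eff(nu_min) - R2,eff(nu_max)
    with the error by quadrature.  ``mode="intensity"`` instead returns
    the literal intensity difference I(nu_min) - I(nu_max) reconstructed
    from the reference intensity.  The returned metadata carries the
    caveat that endpoint subtraction underestimates the Rex error.
    """
    i_lo = int(np.argmin(curve.nu_unique))
    i_hi = int(np.argmax(curve.nu_unique))
    if i_lo == i_hi:
        raise ValueError("curve must contain distinct lowest and highest nu points")
    if mode == "r2eff":
        value = curve.r2eff[i_lo] - curve.r2eff[i_hi]
        error = math.hypot(curve.r2eff_error[i_lo], curve.r2eff_error[i_hi])
    elif mode == "intensity":
        i0, T = curve.reference_intensity, curve.settings.T_relax
        if not np.isfinite(i0):
            raise ValueError("intensity mode requires a reference intensity")
        ints = i0 * np.exp(-curve.r2eff * T)
        sigs = ints * T * curve.r2eff_error
        value = ints[i_lo] - ints[i_hi]
        error = math.hypot(sigs[i_lo], sigs[i_hi])
    else:
        raise ValueError(f"unknown Rex mode {mode!r}")
    return {"rex": float(value), "rex_error": float(error), "mode": mode,
            "nu_low": float(curve.nu_unique[i_lo]),
            "nu_high": float(curve.nu_unique[i_hi]),
            "caveat": REX_CAVEAT}


def _expm2(m: np.ndarray) -> np.ndarray:
    """Closed-form matrix exponential of a 2x2 complex matrix.

    Written in terms of the eigenvalue exponentials e^(h +/- q) (h the
    half-trace) so it stays finite for strongly damped blocks where
    cosh(q) alone would overflow.
    """
    half_tr = 0.5 * (m[0, 0] + m[1, 1])
    a = m - half_tr * np.eye(2)
    q = np.sqrt(a[0, 0] ** 2 + a[0, 1] * a[1, 0] + 0j)
    if abs(q) < 1e-8:
        return np.exp(half_tr) * (np.eye(2) + a)
    e_plus = np.exp(half_tr + q)
    e_minus = np.exp(half_tr - q)
    return 0.5 * ((e_plus + e_minus) * np.eye(2)
                  + (e_plus - e_minus) / q * a)


_EYE2 = np.eye(2, dtype=complex)


def _expm2_batch(m: np.ndarray) -> np.ndarray:
    """Closed-form exponential of a stack of 2x2 complex matrices (k,2,2)."""
    half_tr = 0.5 * (m[:, 0, 0] + m[:, 1, 1])
    a = m - half_tr[:, None, None] * _EYE2
    q = np.sqrt(a[:, 0, 0] ** 2 + a[:, 0, 1] * a[:, 1, 0] + 0j)
    small = np.abs(q) < 1e-8
    q_safe = np.where(small, 1.0, q)
    e_plus = np.exp(half_tr + q)
    e_minus = np.exp(half_tr - q)
    c_eye = 0.5 * (e_plus + e_minus)
    c_a = np.where(small, np.exp(half_tr), 0.5 * (e_plus - e_minus) / q_safe)
    return c_eye[:, None, None] * _EYE2 + c_a[:, None, None] * a


def _matpow_batch(m: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Per-row integer powers of a stack of 2x2 matrices (binary powering)."""
    out = np.broadcast_to(_EYE2, m.shape).copy()
    base = m.copy()
    n = n.astype(int).copy()
    while np.any(n > 0):
        odd = (n & 1) == 1
        if np.any(odd):
            out[odd] = np.einsum("kij,kjl->kil", out[odd], base[odd])
        n >>= 1
        if np.any(n > 0):
            base = np.einsum("kij,kjl->kil", base, base)
    return out


def _propagate_r2eff(nu: np.ndarray, T: float, k_ab: float, k_ba: float,
                     dw_refocused: float, dw_static: float, r2_0: float
                     ) -> np.ndarray:
    """R2,eff(nu) by numerical propagation of the two-state coherence.

    ``dw_refocused`` is the part of the minor-state phase offset (rad/s)
    whose sign is conjugated by each refocusing pulse (13C for MQ, the
    probe nucleus itself for SQ); ``dw_static`` is the part the pulses
    do not touch (the 1H contribution to the MQ phase; zero for SQ).
    The detected signal is the major-state (A) coherence — the peak
    actually integrated in the spectrum — starting from equilibrium
    populations and normalized by its initial value, averaged over the
    two starting branches (e.g. DQ and ZQ, both created by an HMQC
    transfer); intrinsic relaxation r2_0 is uniform across states and
    added analytically.
    """
    if k_ab + k_ba <= 0:
        return np.full(len(nu), float(r2_0))
    n = np.rint(np.asarray(nu, dtype=float) * T).astype(int)
    if np.any(n < 1):
        raise ValueError(f"nu values {np.asarray(nu)[n < 1]} with T={T} give "
                         f"no complete CPMG cycle")
    k = len(n)
    rates = _propagate_rows(np.full(k, T), n, k_ab, k_ba,
                            np.full(k, float(dw_refocused)),
                            np.full(k, float(dw_static)))
    return r2_0 + rates


def _propagate_rows(T_rows: np.ndarray, n: np.ndarray, k_ab: float, k_ba: float,
                    dw_ref: np.ndarray, dw_stat: np.ndarray) -> np.ndarray:
    """Exchange contribution to R2,eff for a stack of CPMG rows, each with
    its own relaxation period, cycle count and rad/s shift differences."""
    p_b = k_ab / (k_ab + k_ba)
    p_a = 1.0 - p_b
    p0 = np.array([p_a, p_b], dtype=complex)
    tau = T_rows / (4.0 * n)  # one cycle = tau-180-2tau-180-tau
    k = len(n)
    lam_plus = np.zeros((k, 2, 2), dtype=complex)
    lam_plus[:, 0, 0] = -k_ab
    lam_plus[:, 0, 1] = k_ba
    lam_plus[:, 1, 0] = k_ab
    lam_minus = lam_plus.copy()
    lam_plus[:, 1, 1] = -k_ba + 1j * (dw_stat + dw_ref)
    lam_minus[:, 1, 1] = -k_ba + 1j * (dw_stat - dw_ref)
    t1 = tau[:, None, None]
    e_p = _expm2_batch(lam_plus * t1)
    e_m = _expm2_batch(lam_minus * t1)
    e_p2 = _expm2_batch(lam_plus * 2.0 * t1)
    e_m2 = _expm2_batch(lam_minus * 2.0 * t1)
    cyc_plus = np.einsum("kij,kjl,klm->kim", e_p, e_m2, e_p)
    cyc_minus = np.einsum("kij,kjl,klm->kim", e_m, e_p2, e_m)
    u_plus = _matpow_batch(cyc_plus, n)
    u_minus = _matpow_batch(cyc_minus, n)
    sig = 0.5 * (np.abs(u_plus @ p0)[:, 0] + np.abs(u_minus @ p0)[:, 0]) / p_a
    return -np.log(np.maximum(sig, 1e-300)) / T_rows


def mq_model_r2eff(kex: float, p_b: float, dw_c_ppm: float, dw_h_ppm: float,
                   r2_0: float, settings: CPMGSettings,
                   nu: Optional[np.ndarray] = None) -> np.ndarray:
    """Two-state 13C multiple-quantum CPMG model curve.

    The minor-state MQ phase offsets are dw_H + dw_C (double quantum)
    and dw_H - dw_C (zero quantum) in rad/s at the given field; each
    13C 180 pulse swaps the branches.  With p_b = 0, vanishing shift
    differences, or very fast exchange the curve is flat at r2_0.  The
    curve is invariant under a simultaneous sign flip of (dw_C, dw_H).
    """
    nu = settings.nu_cpmg if nu is None else np.asarray(nu, dtype=float)
    dw_c = dw_ppm_to_rad(dw_c_ppm, settings.field_1H, "C")
    dw_h = dw_ppm_to_rad(dw_h_ppm, settings.field_1H, "H")
    k_ab, k_ba = p_b * kex, (1.0 - p_b) * kex
    return _propagate_r2eff(nu, settings.T_relax, k_ab, k_ba,
                            dw_refocused=dw_c, dw_static=dw_h, r2_0=r2_0)


def sq_model_r2eff(kex: float, p_b: float, dw_ppm: float, r2_0: float,
                   settings: CPMGSettings,
                   nu: Optional[np.ndarray] = None) -> np.ndarray:
    """Two-state single-quantum CPMG model curve.

    Same numerical propagation as the MQ model, with the refocusing
    pulses conjugating the full phase of the probe nucleus and no
    static term.  Exact at any cycle count; the Carver-Richards closed
    form (:func:`carver_richards_r2eff`) reproduces it in the
    many-cycle limit and the Luz-Meiboom expression in fast exchange.
    """
    nu = settings.nu_cpmg if nu is None else np.asarray(nu, dtype=float)
    nucleus = "H" if settings.coherence == "SQ_1H" else "C"
    dw = dw_ppm_to_rad(dw_ppm, settings.field_1H, nucleus)
    k_ab, k_ba = p_b * kex, (1.0 - p_b) * kex
    return _propagate_r2eff(nu, settings.T_relax, k_ab, k_ba,
                            dw_refocused=dw, dw_static=0.0, r2_0=r2_0)


def carver_richards_r2eff(kex: float, p_b: float, dw_ppm: float, r2_0: float,
                          settings: CPMGSettings,
                          nu: Optional[np.ndarray] = None) -> np.ndarray:
    """Carver-Richards closed-form two-state SQ dispersion.

    Gives the asymptotic (dominant-eigenvalue) decay rate; it neglects
    the initial-condition projection onto the decaying modes and so
    deviates from exact propagation at small cycle counts, most visibly
    in slow exchange.  Kept as an independent analytic cross-check.
    """
    nu = settings.nu_cpmg if nu is None else np.asarray(nu, dtype=float)
    nucleus = "H" if settings.coherence == "SQ_1H" else "C"
    dw = dw_ppm_to_rad(dw_ppm, settings.field_1H, nucleus)
    if p_b == 0.0 or dw == 0.0:
        return np.full(len(nu), float(r2_0))
    p_a = 1.0 - p_b
    psi = kex ** 2 - dw ** 2
    zeta = -2.0 * dw * kex * (p_a - p_b)
    root = math.hypot(psi, zeta)
    d_plus = 0.5 * (1.0 + (psi + 2.0 * dw ** 2) / root)
    d_minus = 0.5 * (-1.0 + (psi + 2.0 * dw ** 2) / root)
    eta_plus = np.sqrt(max(root + psi, 0.0) / 2.0) / (2.0 * nu)
    eta_minus = np.sqrt(max(root - psi, 0.0) / 2.0) / (2.0 * nu)
    # guard the acosh argument against round-off below 1
    arg = np.maximum(d_plus * np.cosh(eta_plus) - d_minus * np.cos(eta_minus), 1.0)
    return r2_0 + 0.5 * kex - nu * np.arccosh(arg)


def luz_meiboom_r2eff(kex: float, p_b: float, dw: float, r2_0: float,
                      nu: np.ndarray) -> np.ndarray:
    """Fast-exchange (Luz-Meiboom) closed form; ``dw`` in rad/s."""
    nu = np.asarray(nu, dtype=float)
    phi = (1.0 - p_b) * p_b * dw ** 2
    return r2_0 + (phi / kex) * (1.0 - (4.0 * nu / kex)
                                 * np.tanh(kex / (4.0 * nu)))


def model_curve(kex: float, p_b: float, dw_c_ppm: float, dw_h_ppm: float,
                r2_0: float, settings: CPMGSettings,
                nu: Optional[np.ndarray] = None) -> np.ndarray:
    """Dispatch on the settings' coherence type (MQ numeric / SQ closed form)."""
    if settings.coherence == "MQ_13C":
        return mq_model_r2eff(kex, p_b, dw_c_ppm, dw_h_ppm, r2_0, settings, nu)
    return sq_model_r2eff(kex, p_b, dw_h_ppm, r2_0, settings, nu)


DEFAULT_KEX_STARTS = (100.0, 400.0, 1600.0)
DEFAULT_PB_STARTS = (0.03, 0.10)


def fit_dispersion_global(curves: Sequence[DispersionCurve],
                          kex_starts: Sequence[float] = DEFAULT_KEX_STARTS,
                          pb_starts: Sequence[float] = DEFAULT_PB_STARTS,
                          seed: int = 0) -> GroupFitResult:
    """Global two-state fit sharing kex and p_b across all curves.

    Shift differences are shared per probe (dw_C and dw_H for MQ
    probes, dw_H for SQ probes; dw_C is constrained >= 0 because its
    sign is unidentifiable from CPMG data alone) and the exchange-free
    baseline R2_0 is fitted per curve (probe x field).  Chi-square with
    weights 1/sigma^2(R2,eff) is minimized by profiling: the baselines
    are eliminated analytically, the remaining parameters are fitted at
    each point of a log-spaced kex grid spanning ``kex_starts`` (inner
    fits multi-started over ``pb_starts`` at the first point, then warm
    started), and the profile minimum is refined parabolically.  The
    kex uncertainty comes from the profile curvature (delta chi^2 = 1),
    scaled by sqrt(reduced chi^2) when that exceeds one; other
    parameter errors come from the full covariance at the optimum.  A
    fit driven to the p_b bound or with negligible model dispersion is
    flagged "no detectable exchange" rather than reported as a rate.
    """
    if not curves:
        raise ValueError("at least one dispersion curve is required")
    probes = sorted({c.probe_id for c in curves})
    probe_is_mq = {p: any(c.probe_id == p and c.settings.coherence == "MQ_13C"
                          for c in curves) for p in probes}
    # nonlinear parameter layout: [kex, pb] + per-probe dw (dwC then dwH
    # for MQ probes, dwH only for SQ-only probes).  The per-curve
    # baselines R2_0 enter the model additively and are profiled out
    # analytically at every step (variable projection), which keeps the
    # nonlinear problem small and well conditioned.
    idx: dict[str, int] = {"kex": 0, "pb": 1}
    pos = 2
    for p in probes:
        if probe_is_mq[p]:
            idx[f"dwC:{p}"] = pos
            pos += 1
        idx[f"dwH:{p}"] = pos
        pos += 1
    n_nl = pos
    n_params = n_nl + len(curves)  # including the profiled baselines
    n_data = sum(len(c.r2eff) for c in curves)
    if n_params >= n_data:
        raise ValueError(
            f"under-determined grouping: {n_params} parameters for {n_data} points")

    weights = [1.0 / c.r2eff_error ** 2 for c in curves]

    # stack every curve's rows so one batched propagation serves the
    # whole group per objective evaluation.  MQ rows: refocused part is
    # the 13C shift difference, static part the 1H one; SQ rows:
    # refocused part is the probe nucleus' own shift difference.
    slices: list[slice] = []
    row_T, row_n, row_iref, row_rfac, row_istat, row_sfac = [], [], [], [], [], []
    pos_r = 0
    for c in curves:
        m = len(c.nu_unique)
        slices.append(slice(pos_r, pos_r + m))
        pos_r += m
        row_T.append(np.full(m, c.settings.T_relax))
        row_n.append(np.rint(c.nu_unique * c.settings.T_relax).astype(int))
        hfac = dw_ppm_to_rad(1.0, c.settings.field_1H, "H")
        if c.settings.coherence == "MQ_13C":
            row_iref.append(np.full(m, idx[f"dwC:{c.probe_id}"]))
            row_rfac.append(np.full(m, dw_ppm_to_rad(1.0, c.settings.field_1H, "C")))
            row_istat.append(np.full(m, idx[f"dwH:{c.probe_id}"]))
            row_sfac.append(np.full(m, hfac))
        else:
            row_iref.append(np.full(m, idx[f"dwH:{c.probe_id}"]))
            row_rfac.append(np.full(m, hfac))
            row_istat.append(np.full(m, idx["pb"]))  # dummy, zero factor
            row_sfac.append(np.zeros(m))
    row_T = np.concatenate(row_T)
    row_n = np.concatenate(row_n)
    row_iref = np.concatenate(row_iref).astype(int)
    row_rfac = np.concatenate(row_rfac)
    row_istat = np.concatenate(row_istat).astype(int)
    row_sfac = np.concatenate(row_sfac)

    def all_dispersions(x: np.ndarray) -> list[np.ndarray]:
        """Per-curve exchange contributions (zero baseline)."""
        kex, pb = x[idx["kex"]], x[idx["pb"]]
        k_ab, k_ba = pb * kex, (1.0 - pb) * kex
        stacked = _propagate_rows(row_T, row_n, k_ab, k_ba,
                                  x[row_iref] * row_rfac,
                                  x[row_istat] * row_sfac)
        return [stacked[s] for s in slices]

    def profiled_baselines(x: np.ndarray) -> list[float]:
        return [float(np.sum(w * (c.r2eff - d)) / np.sum(w))
                for c, w, d in zip(curves, weights, all_dispersions(x))]

    def residuals(x: np.ndarray) -> np.ndarray:
        parts = []
        for c, w, d in zip(curves, weights, all_dispersions(x)):
            r20 = np.sum(w * (c.r2eff - d)) / np.sum(w)
            parts.append((d + r20 - c.r2eff) / c.r2eff_error)
        return np.concatenate(parts)

    lo = np.zeros(n_nl)
    hi = np.full(n_nl, np.inf)
    lo[idx["kex"]], hi[idx["kex"]] = 1.0, 1e5
    lo[idx["pb"]], hi[idx["pb"]] = 1e-4, 0.499
    for key, j in idx.items():
        if key.startswith("dwC:"):
            lo[j], hi[j] = 0.0, 10.0
        elif key.startswith("dwH:"):
            lo[j], hi[j] = (-3.0 if probe_is_mq[key[4:]] else 0.0), 3.0

    # Inner problem: with kex fixed, minimize over [pb, dw...].  The
    # chi-square profile over kex is then scanned on a log grid with
    # warm starts and the minimum refined parabolically; this avoids the
    # long, flat (kex, pb, dw) valleys that defeat a joint descent and
    # yields the kex uncertainty from the profile curvature.
    lo_in, hi_in = lo[1:], hi[1:]
    x_scale_in = np.ones(n_nl - 1)
    x_scale_in[0] = 0.01  # pb
    x_scale_in[1:] = 0.1  # shift differences

    def inner_fit(kex_val: float, y0: np.ndarray, tight: bool = False):
        def inner_res(y: np.ndarray) -> np.ndarray:
            return residuals(np.concatenate([[kex_val], y]))
        tol = 1e-9 if tight else 1e-7
        return least_squares(inner_res, y0, bounds=(lo_in, hi_in),
                             x_scale=x_scale_in, xtol=tol, ftol=tol,
                             max_nfev=120 * n_nl)

    def starts() -> list[np.ndarray]:
        out = []
        for pb0 in pb_starts:
            for dw0 in (0.2, 0.8):
                y0 = np.full(n_nl - 1, 0.1)
                y0[0] = pb0
                for key, j in idx.items():
                    if key.startswith("dwC:"):
                        y0[j - 1] = dw0
                out.append(y0)
        return out

    kex_grid = np.geomspace(min(kex_starts), max(kex_starts), 9)
    profile: list[tuple[float, float, np.ndarray]] = []
    warm: list[np.ndarray] = starts()
    for kex_val in kex_grid:
        best_in = None
        for y0 in warm:
            sol = inner_fit(kex_val, y0)
            if best_in is None or sol.cost < best_in.cost:
                best_in = sol
        profile.append((kex_val, best_in.cost, best_in.x))
        # keep fresh starts alongside the warm chain so one bad basin
        # cannot poison the rest of the profile
        warm = [best_in.x] + starts()[:2]
    # parabolic refinement around the grid minimum (in log kex)
    i_min = int(np.argmin([c for _, c, _ in profile]))
    for _ in range(3):
        k_c, c_c, y_c = profile[i_min]
        neighbors = sorted(profile, key=lambda t: abs(math.log(t[0] / k_c)))[:3]
        ks = np.log([t[0] for t in neighbors])
        cs = np.array([t[1] for t in neighbors])
        if len(np.unique(ks)) < 3:
            break
        a, b, _c0 = np.polyfit(ks, cs, 2)
        if a <= 0:
            break
        k_new = float(np.exp(-b / (2 * a)))
        k_new = min(max(k_new, lo[idx["kex"]]), hi[idx["kex"]])
        if any(abs(math.log(k_new / t[0])) < 1e-4 for t in profile):
            break
        sol = inner_fit(k_new, y_c, tight=True)
        profile.append((k_new, sol.cost, sol.x))
        i_min = int(np.argmin([c for _, c, _ in profile]))
    kex_best, cost_best, y_best = profile[i_min]

    # kex SE from the profile-likelihood curvature: delta chi^2 = 1
    prof_sorted = sorted(profile, key=lambda t: abs(math.log(t[0] / kex_best)))[:5]
    ks = np.array([t[0] for t in prof_sorted])
    cs = np.array([2.0 * t[1] for t in prof_sorted])  # chi^2 = 2*cost
    kex_se = float("nan")
    if len(np.unique(ks)) >= 3:
        a2 = np.polyfit(ks, cs, 2)[0]
        if a2 > 0:
            kex_se = 1.0 / math.sqrt(a2)

    x = np.concatenate([[kex_best], y_best])
    dof = max(n_data - n_params, 1)
    redchi = 2.0 * cost_best / dof
    baselines = profiled_baselines(x)

    # covariance from the FULL weighted Jacobian (nonlinear + baselines),
    # by central finite differences at the optimum
    def full_residuals(xfull: np.ndarray) -> np.ndarray:
        disp = all_dispersions(xfull[:n_nl])
        return np.concatenate([(disp[i] + xfull[n_nl + i] - c.r2eff)
                               / c.r2eff_error for i, c in enumerate(curves)])

    xfull = np.concatenate([x, baselines])
    steps = np.concatenate([[1e-3 * max(kex_best, 1.0)],
                            np.full(n_nl - 1, 1e-5) + 1e-4 * x_scale_in,
                            np.full(len(curves), 1e-5)])
    jac = np.empty((n_data, n_params))
    for j in range(n_params):
        xp, xm = xfull.copy(), xfull.copy()
        xp[j] += steps[j]
        xm[j] -= steps[j]
        jac[:, j] = (full_residuals(xp) - full_residuals(xm)) / (2 * steps[j])
    try:
        cov = np.linalg.inv(jac.T @ jac)
        perr = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        perr = np.full(n_params, np.nan)
    kex, pb = float(x[idx["kex"]]), float(x[idx["pb"]])
    dw_c = {p: float(x[idx[f"dwC:{p}"]]) for p in probes if probe_is_mq[p]}
    dw_h = {p: float(x[idx[f"dwH:{p}"]]) for p in probes}
    r2_0 = {(c.probe_id, c.settings.field_1H): max(float(b), 0.0)
            for c, b in zip(curves, baselines)}
    final_disp = all_dispersions(x)
    per_curve = {i: (final_disp[i] + baselines[i] - c.r2eff) / c.r2eff_error
                 for i, c in enumerate(curves)}
    max_disp = max(float(np.ptp(d)) for d in final_disp)
    no_exchange = bool(pb <= 2e-4 or max_disp < 0.5)
    params = ExchangeParams(kex=kex, p_b=min(max(pb, 1e-4), 0.499),
                            dw_C=dw_c, dw_H=dw_h, r2_0=r2_0)
    if not math.isfinite(kex_se) or kex_se <= 0:
        kex_se = float(perr[idx["kex"]])  # covariance fallback
    # inflate for misassigned replicate errors (standard chi^2 scaling)
    kex_se *= math.sqrt(max(redchi, 1.0))
    return GroupFitResult(
        params=params,
        kex_error=float(kex_se),
        pb_error=float(perr[idx["pb"]]),
        redchi=float(redchi),
        per_curve_residuals=per_curve,
        converged=True,
        n_data=n_data,
        n_params=n_params,
        no_detectable_exchange=no_exchange,
        message=("no detectable exchange" if no_exchange else
                 "sign of dw_C is unidentifiable from CPMG alone; "
                 "reported as |dw_C|"),
    )
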