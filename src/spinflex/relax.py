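"""Spin-relaxation analysis: single-exponential R1/R1rho fitting with
Monte Carlo errors, rotating-frame to transverse-rate conversion, and
heteronuclear NOE with propagated errors.

The decay model is I(t) = I0 * exp(-R * t); no multi-exponential model
is attempted.  Rate uncertainties come from Monte Carlo resampling of
the measured peak heights (Gaussian, centred on the measured value with
width equal to the height error), refitting each replicate and taking
the standard deviation across replicates.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .types import NOEResult, Peak, RateResult, RelaxSeries, SpinLockSettings

__all__ = [
    "fit_exponential",
    "monte_carlo_error",
    "fit_rate_with_error",
    "r1rho_to_r2",
    "compute_noe",
    "baseline_and_flags",
]


def _decay(t: np.ndarray, i0: float, rate: float) -> np.ndarray:
    return i0 * np.exp(-rate * t)


def _start_values(series: RelaxSeries) -> tuple[float, float]:
    """Deterministic analytic start values: I0 from the maximum intensity,
    R from a log-linear regression over the positive intensities."""
    i0 = float(np.max(series.intensities))
    pos = series.intensities > 0
    if pos.sum() >= 2 and i0 > 0:
        slope = np.polyfit(series.delays[pos], np.log(series.intensities[pos]), 1)[0]
        rate0 = max(-float(slope), 0.0)
    else:
        rate0 = 1.0
    return (i0 if i0 > 0 else 1.0), rate0


def fit_exponential(series: RelaxSeries) -> RateResult:
    """Weighted least-squares fit of I0*exp(-R*t) to one decay series.

    Returns point estimates only; uncertainties are the job of
    :func:`monte_carlo_error`.  Non-convergence is reported on the
    result (``converged=False`` with a diagnostic message), never as a
    silent NaN.
    """
    if not series.fittable:
        return RateResult(series.residue_id, series.experiment,
                          float("nan"), float("nan"), converged=False,
                          message="unfittable: fewer than 2 distinct delays")
    p0 = _start_values(series)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(_decay, series.delays, series.intensities,
                                p0=p0, sigma=series.intensity_errors,
                                absolute_sigma=True, maxfev=5000)
    except RuntimeError as exc:
        return RateResult(series.residue_id, series.experiment,
                          float("nan"), float("nan"), converged=False,
                          message=f"fit did not converge: {exc}")
    i0, rate = float(popt[0]), float(popt[1])
    residuals = series.intensities - _decay(series.delays, i0, rate)
    return RateResult(series.residue_id, series.experiment, rate, i0,
                      residuals=residuals)


def monte_carlo_error(series: RelaxSeries, fit: RateResult, n_mc: int = 500,
                      seed: int | np.random.Generator = 0,
                      max_failure_fraction: float = 0.10
                      ) -> tuple[float, float]:
    """Monte Carlo rate and amplitude errors for an exponential fit.

    Each of the ``n_mc`` replicates resamples every intensity from a
    Gaussian centred on the MEASURED value with width equal to its
    error, refits the decay, and the standard deviations of the
    replicate (R, I0) estimates are returned.  A fixed seed makes the
    result reproducible.  More than ``max_failure_fraction`` replicate
    non-convergence raises with diagnostics.
    """
    if n_mc < 2:
        raise ValueError("n_mc must be >= 2")
    if not fit.converged:
        raise ValueError("cannot estimate errors for a non-converged fit")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rates = np.empty(n_mc)
    amps = np.empty(n_mc)
    failures = 0
    p0 = (fit.amplitude, fit.rate)
    for k in range(n_mc):
        resampled = rng.normal(series.intensities, series.intensity_errors)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(_decay, series.delays, resampled, p0=p0,
                                    sigma=series.intensity_errors,
                                    absolute_sigma=True, maxfev=2000)
            amps[k], rates[k] = popt
        except RuntimeError:
            failures += 1
            amps[k] = rates[k] = np.nan
    if failures > max_failure_fraction * n_mc:
        raise RuntimeError(
            f"residue {series.residue_id}: {failures}/{n_mc} Monte Carlo "
            f"replicates failed to converge"
        )
    return float(np.nanstd(rates, ddof=1)), float(np.nanstd(amps, ddof=1))


def fit_rate_with_error(series: RelaxSeries, n_mc: int = 500,
                        seed: int | np.random.Generator = 0) -> RateResult:
    """Convenience wrapper: point fit plus Monte Carlo uncertainties."""
    fit = fit_exponential(series)
    if not fit.converged:
        return fit
    rate_err, amp_err = monte_carlo_error(series, fit, n_mc=n_mc, seed=seed)
    fit.rate_error = rate_err
    fit.amplitude_error = amp_err
    fit.n_mc = n_mc
    return fit


def r1rho_to_r2(r1rho: RateResult, r1: RateResult,
                sl: SpinLockSettings) -> tuple[float, float]:
    """Convert a rotating-frame rate to R2 with the offset correction.

    R2 = R1rho / sin^2(theta) - R1 / tan^2(theta), where
    theta = atan(omega / Omega) is the effective-field tilt angle.  The
    error is first-order propagation treating R1rho and R1 as
    independent.  On resonance (Omega = 0, theta = 90 deg) R2 equals
    R1rho exactly.
    """
    if r1rho.residue_id != r1.residue_id:
        raise ValueError("R1rho and R1 results must be for the same residue")
    if sl.omega_sl == 0 and sl.offset == 0:
        raise ValueError("theta undefined: spin-lock field and offset both zero")
    theta = math.radians(sl.theta_deg)
    s2, t2 = math.sin(theta) ** 2, math.tan(theta) ** 2
    r2 = r1rho.rate / s2 - r1.rate / t2
    err = math.sqrt((r1rho.rate_error / s2) ** 2 + (r1.rate_error / t2) ** 2)
    return r2, err


def compute_noe(sat: Peak, ref: Peak) -> NOEResult:
    """Heteronuclear NOE as the ratio of saturated to reference height.

    noe = I_sat / I_ref with standard error propagation
    sigma = |noe| * sqrt((s_sat/I_sat)^2 + (s_ref/I_ref)^2); a zero
    saturated height is allowed (noe 0, error s_sat/|I_ref|), a zero
    reference height is not.
    """
    if sat.residue_id != ref.residue_id:
        raise ValueError("saturated and reference peaks must be the same residue")
    if ref.height == 0:
        raise ValueError(f"residue {ref.residue_id}: reference height is zero")
    noe = sat.height / ref.height
    if sat.height == 0:
        err = sat.height_error / abs(ref.height)
    else:
        err = abs(noe) * math.sqrt((sat.height_error / sat.height) ** 2
                                   + (ref.height_error / ref.height) ** 2)
    return NOEResult(sat.residue_id, noe, err)


def baseline_and_flags(r1_values: dict[int, float], noe_values: dict[int, float],
                       helix_ranges: Sequence[tuple[int, int]],
                       k: float = 2.0) -> dict:
    """Flag residues with enhanced ps-ns dynamics relative to the helical
    baseline.

    The baseline for each parameter is the mean +/- SD over residues in
    the annotated helical ranges (inclusive).  A residue is flagged when
    its R1 exceeds baseline + k*SD AND its NOE falls below
    baseline - k*SD — the joint signature of fast internal motion.
    Requires at least five helical residues with data.
    """
    if not helix_ranges:
        raise ValueError("helical annotation is required")
    helical = {r for lo, hi in helix_ranges for r in range(lo, hi + 1)}
    common = sorted(set(r1_values) & set(noe_values))
    helix_with_data = [r for r in common if r in helical]
    if len(helix_with_data) < 5:
        raise ValueError(
            f"need >= 5 helical residues with data, have {len(helix_with_data)}"
        )
    r1_base = np.array([r1_values[r] for r in helix_with_data])
    noe_base = np.array([noe_values[r] for r in helix_with_data])
    r1_mean, r1_sd = float(r1_base.mean()), float(r1_base.std(ddof=1))
    noe_mean, noe_sd = float(noe_base.mean()), float(noe_base.std(ddof=1))
    flagged = [r for r in common
               if r1_values[r] > r1_mean + k * r1_sd
               and noe_values[r] < noe_mean - k * noe_sd]
    return {
        "r1_baseline": (r1_mean, r1_sd),
        "noe_baseline": (noe_mean, noe_sd),
        "k": k,
        "flagged": flagged,
    }
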