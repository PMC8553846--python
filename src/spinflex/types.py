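"""Shared domain containers for the analysis pipeline.

Unit conventions (fixed at the I/O boundary, never converted elsewhere):
delays and relaxation periods in seconds, rates and nu_CPMG in s^-1,
chemical shifts in ppm, spectrometer fields as the 1H frequency in MHz,
spin-lock field strengths and offsets in Hz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "Peak",
    "PeakTable",
    "PipelineConfig",
    "RelaxSeries",
    "RateResult",
    "SpinLockSettings",
    "NOEResult",
    "CSPWeights",
    "CSPRecord",
    "PeakCluster",
    "CPMGSettings",
    "DispersionCurve",
    "ExchangeParams",
    "GroupFitResult",
]

#: Fractional intensity error floor assumed when the base-plane noise
#: estimate falls below it.
DEFAULT_ERROR_FLOOR = 0.02


@dataclass
class Peak:
    """A single 2D resonance: position, height and height uncertainty."""

    residue_id: int
    atom_label: str
    shift_w1: float
    shift_w2: float
    height: float
    height_error: float

    def __post_init__(self) -> None:
        if not self.height_error > 0:
            raise ValueError(
                f"Peak {self.residue_id}{self.atom_label}: height_error must be > 0, "
                f"got {self.height_error}"
            )


@dataclass
class PeakTable:
    """Peaks measured under one ionic condition at one field."""

    condition_label: str
    peaks: list[Peak] = field(default_factory=list)
    field_1H: Optional[float] = None  # MHz

    def __post_init__(self) -> None:
        seen: set[tuple[int, str]] = set()
        for p in self.peaks:
            key = (p.residue_id, p.atom_label)
            if key in seen:
                raise ValueError(f"duplicate peak for residue {key[0]} atom {key[1]!r}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.peaks)

    def get(self, residue_id: int, atom_label: str) -> Optional[Peak]:
        for p in self.peaks:
            if p.residue_id == residue_id and p.atom_label == atom_label:
                return p
        return None


@dataclass
class CSPWeights:
    """Gyromagnetic-ratio weights for the heteronucleus term of the CSP.

    W = |gamma_X / gamma_H| truncated to three decimals: 0.101 for 15N
    (amide CSPs) and 0.251 for 13C (methyl CSPs).
    """

    W_N: float = 0.101
    W_C: float = 0.251

    def __post_init__(self) -> None:
        for name, w in (("W_N", self.W_N), ("W_C", self.W_C)):
            if not 0 < w < 1:
                raise ValueError(f"{name} must be in (0, 1), got {w}")


@dataclass
class PipelineConfig:
    """Run-level knobs shared by every stage.

    ``mc_replicates`` (default 500) is the Monte Carlo sample size for
    rate errors; ``error_floor`` the fractional intensity-error floor;
    ``threshold_sigma_factor``/``trim_fraction`` parameterize the CSP
    significance rule (1.5 sigma above the 10% trimmed mean).
    """

    weights: CSPWeights = field(default_factory=CSPWeights)
    mc_replicates: int = 500
    error_floor: float = DEFAULT_ERROR_FLOOR
    threshold_sigma_factor: float = 1.5
    trim_fraction: float = 0.10
    seed: int = 0
    experiments: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mc_replicates < 2:
            raise ValueError("mc_replicates must be >= 2")
        if not 0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must be in [0, 0.5)")
        if self.error_floor < 0:
            raise ValueError("error_floor must be >= 0")


@dataclass
class RelaxSeries:
    """Intensity-vs-delay measurements for one residue and experiment."""

    residue_id: int
    experiment: str  # "R1" or "R1rho"
    delays: np.ndarray  # seconds
    intensities: np.ndarray
    intensity_errors: np.ndarray

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.intensity_errors = np.asarray(self.intensity_errors, dtype=float)
        if not (len(self.delays) == len(self.intensities) == len(self.intensity_errors)):
            raise ValueError("delays, intensities and errors must have equal length")
        if np.any(self.intensity_errors <= 0):
            raise ValueError("all intensity errors must be > 0")

    @property
    def n_points(self) -> int:
        return len(self.delays)

    @property
    def fittable(self) -> bool:
        """At least two points at distinct delays are needed for a decay fit."""
        return self.n_points >= 2 and len(np.unique(self.delays)) >= 2


@dataclass
class RateResult:
    """Fitted single-exponential decay I0*exp(-R*t) for one residue."""

    residue_id: int
    experiment: str
    rate: float  # s^-1
    amplitude: float
    rate_error: float = float("nan")
    amplitude_error: float = float("nan")
    n_mc: int = 0
    converged: bool = True
    residuals: Optional[np.ndarray] = None
    message: str = ""


@dataclass
class SpinLockSettings:
    """Rotating-frame experiment geometry.

    theta = atan(omega_sl / offset) is the tilt angle of the effective
    field; on resonance (offset 0) theta is 90 degrees and R1rho = R2.
    """

    omega_sl: float  # Hz, spin-lock field strength
    offset: float = 0.0  # Hz, resonance offset from the carrier

    def __post_init__(self) -> None:
        if not self.omega_sl > 0:
            raise ValueError("spin-lock field strength must be > 0")

    @property
    def theta_deg(self) -> float:
        if self.offset == 0.0:
            return 90.0
        return math.degrees(math.atan2(self.omega_sl, abs(self.offset)))


@dataclass
class NOEResult:
    """Heteronuclear NOE: ratio of saturated to reference peak height."""

    residue_id: int
    noe: float
    noe_error: float

    def __post_init__(self) -> None:
        if not self.noe_error > 0:
            raise ValueError("noe_error must be > 0")


@dataclass
class CSPRecord:
    """Weighted shift difference between two conditions for one probe."""

    residue_id: int
    atom_label: str
    delta_H: float  # ppm, condition2 - condition1
    delta_X: float  # ppm, condition2 - condition1 (15N or 13C)
    csp: float  # ppm, >= 0
    significant: bool = False
    comparable: bool = True

    def __post_init__(self) -> None:
        if self.comparable and self.csp < 0:
            raise ValueError("csp must be >= 0")


@dataclass
class PeakCluster:
    """Deconvolved multi-state resonance cluster for one residue."""

    residue_id: int
    positions: list[tuple[float, float]]  # ppm pairs
    linewidths: list[tuple[float, float]]  # ppm HWHM pairs
    amplitudes: list[float]
    fractional_populations: list[float]

    def __post_init__(self) -> None:
        pops = np.asarray(self.fractional_populations, dtype=float)
        if np.any(pops < -1e-9) or np.any(pops > 1 + 1e-9):
            raise ValueError("populations must lie in [0, 1]")
        if abs(pops.sum() - 1.0) > 1e-6:
            raise ValueError("populations must sum to 1 within 1e-6")


@dataclass
class CPMGSettings:
    """Constant-time CPMG design: relaxation period, pulsing rates, field.

    The number of CPMG cycles nu_CPMG * T_relax must be an integer
    (within tolerance) for every pulsing rate; each cycle contains two
    refocusing pulses.
    """

    T_relax: float  # seconds
    nu_cpmg: np.ndarray  # s^-1, replicates appear as repeated values
    field_1H: float  # MHz
    coherence: str  # "MQ_13C" or "SQ_1H"
    cycle_tol: float = 0.05

    def __post_init__(self) -> None:
        self.nu_cpmg = np.asarray(self.nu_cpmg, dtype=float)
        if not self.T_relax > 0:
            raise ValueError("T_relax must be > 0")
        if np.any(self.nu_cpmg <= 0):
            raise ValueError("all nu_CPMG must be > 0")
        if self.coherence not in ("MQ_13C", "SQ_1H"):
            raise ValueError(f"unknown coherence {self.coherence!r}")
        cycles = self.nu_cpmg * self.T_relax
        off = np.abs(cycles - np.round(cycles))
        if np.any(off > self.cycle_tol):
            bad = self.nu_cpmg[off > self.cycle_tol]
            raise ValueError(
                f"nu_CPMG * T_relax must be an integer cycle count; offending nu: {bad}"
            )

    def n_cycles(self) -> np.ndarray:
        return np.round(self.nu_cpmg * self.T_relax).astype(int)


@dataclass
class DispersionCurve:
    """R2,eff vs nu_CPMG for one probe at one field and coherence."""

    probe_id: str  # e.g. "V64-Cg2"
    settings: CPMGSettings
    r2eff: np.ndarray  # s^-1, replicate-pooled (unique nu values)
    r2eff_error: np.ndarray  # s^-1
    nu_unique: Optional[np.ndarray] = None  # pooled nu grid; defaults to settings grid
    reference_intensity: float = float("nan")

    def __post_init__(self) -> None:
        self.r2eff = np.asarray(self.r2eff, dtype=float)
        self.r2eff_error = np.asarray(self.r2eff_error, dtype=float)
        if self.nu_unique is None:
            self.nu_unique = np.unique(self.settings.nu_cpmg)
        self.nu_unique = np.asarray(self.nu_unique, dtype=float)
        if not (len(self.r2eff) == len(self.r2eff_error) == len(self.nu_unique)):
            raise ValueError("r2eff, errors and nu grid must have equal length")
        if np.any(self.r2eff_error <= 0):
            raise ValueError("all R2,eff errors must be > 0")


@dataclass
class ExchangeParams:
    """Two-state exchange parameter set.

    kex = k_AB + k_BA; p_b the minor-state population; dw_C / dw_H the
    13C and 1H shift differences between states in ppm (per probe);
    r2_0 the exchange-free transverse rate (per probe, per field).
    """

    kex: float  # s^-1
    p_b: float
    dw_C: dict  # probe_id -> ppm
    dw_H: dict  # probe_id -> ppm
    r2_0: dict  # (probe_id, field_1H) -> s^-1

    def __post_init__(self) -> None:
        if not self.kex > 0:
            raise ValueError("kex must be > 0")
        if not 0 < self.p_b < 0.5:
            raise ValueError("p_b must be in (0, 0.5)")
        for key, v in self.r2_0.items():
            if v < 0:
                raise ValueError(f"R2_0 must be >= 0, got {v} for {key}")

    @property
    def k_ab(self) -> float:
        return self.p_b * self.kex

    @property
    def k_ba(self) -> float:
        return (1.0 - self.p_b) * self.kex


@dataclass
class GroupFitResult:
    """Outcome of a (possibly global) two-state dispersion fit."""

    params: ExchangeParams
    kex_error: float
    pb_error: float
    redchi: float
    per_curve_residuals: dict
    converged: bool
    n_data: int
    n_params: int
    no_detectable_exchange: bool = False
    message: str = ""
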