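"""Synthetic-data generators emulating the pipeline's experiments.

Every generator produces inputs with the statistical structure the
analysis assumes — single-exponential decays with a Gaussian noise
model and the 2% error floor, saturated/reference NOE pairs, two-state
MQ/SQ CPMG dispersion intensity tables at multiple static fields,
clusters of overlapping 2D Lorentzian resonances with prescribed
fractional populations, and paired-condition shift tables with a known
perturbed residue set — so every stage is testable without any
experimental download.

Named presets pin the "true" generating values used by the recovery
tests.  Values printed in the literature for the NaK channel (kex of
390 and 356 1/s for the selectivity-filter exchange in Na+, the
86/7/7 and 47/37/16 L48a state populations, the N68 amide NOE of 0.43
in K+) are encoded as generating truths; every quantity the source
does not print (minor-state population p_b, per-probe shift
differences, exchange-free baselines, linewidths, peak positions) is
an assumption of this package, labelled "assumed" in the preset
metadata, and is never itself a recovery target.

Randomness: each generator call derives an independent substream from
(seed, stream label), so adding a generator or reordering calls never
perturbs existing fixtures.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import CPMGSettings, DispersionCurve, ExchangeParams, Peak, RelaxSeries
from . import dispersion as _dsp

__all__ = [
    "substream",
    "gen_decay_series",
    "gen_noe_pair",
    "gen_dispersion_dataset",
    "gen_peak_cluster",
    "gen_csp_tables",
    "PRESETS",
    "R1_DELAYS_NA",
    "NU_CPMG_K_MQ",
    "NU_CPMG_NA_MQ",
    "NU_CPMG_NA_SQ",
    "preset_dispersion_curves",
    "preset_cluster",
    "preset_noe_pair",
]

GENERATOR_VERSION = "1"

#: Longitudinal relaxation delay grid (seconds) for the Na+ sample.
R1_DELAYS_NA = (0.0, 0.4, 1.4, 2.4, 3.6)
#: Rotating-frame relaxation delays (seconds).
R1RHO_DELAYS = (0.002, 0.008, 0.012, 0.018, 0.025)

#: CPMG pulsing-rate grids (s^-1); repeated values are replicates.
NU_CPMG_K_MQ = (50.0, 100.0, 200.0, 200.0, 250.0, 300.0, 350.0, 400.0,
                500.0, 600.0, 600.0, 800.0, 1000.0)
NU_CPMG_NA_MQ = (33.33, 66.67, 100.0, 133.33, 133.33, 166.67, 200.0, 233.33,
                 266.67, 266.67, 300.0, 333.33, 366.67, 400.0, 466.67, 533.33,
                 533.33, 600.0, 666.67, 800.0, 900.0, 1000.0)
NU_CPMG_NA_SQ = (50.0, 100.0, 100.0, 150.0, 200.0, 250.0, 300.0, 350.0,
                 400.0, 400.0, 450.0, 500.0, 600.0, 600.0, 700.0, 800.0,
                 900.0, 1000.0)


def substream(seed: int, label: str) -> np.random.Generator:
    """Independent random substream for (seed, label)."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(label.encode())])


def gen_decay_series(rate: float, i0: float, delays: Sequence[float],
                     noise_fraction: float, seed: int, residue_id: int = 1,
                     experiment: str = "R1") -> RelaxSeries:
    """Synthetic single-exponential decay with Gaussian intensity noise.

    intensities = i0*exp(-rate*t) + Normal(0, noise_fraction*i0); the
    recorded errors are max(noise_fraction*i0, 0.02*|intensity|),
    honouring the 2% floor.
    """
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be >= 0")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    delays = np.asarray(delays, dtype=float)
    if delays.size == 0:
        raise ValueError("delays must be non-empty")
    rng = substream(seed, f"decay:{experiment}:{residue_id}")
    clean = i0 * np.exp(-rate * delays)
    noisy = clean + rng.normal(0.0, noise_fraction * i0, size=delays.shape) \
        if noise_fraction > 0 else clean
    errors = np.maximum(noise_fraction * i0, 0.02 * np.abs(noisy))
    errors = np.maximum(errors, 1e-12 * max(abs(i0), 1.0))
    return RelaxSeries(residue_id, experiment, delays, noisy, errors)


def gen_noe_pair(noe_true: float, i_ref: float, noise_fraction: float,
                 seed: int, residue_id: int = 68,
                 atom_label: str = "N-H") -> tuple[Peak, Peak]:
    """Saturated/reference peak pair for a heteronuclear NOE experiment.

    The saturated height is centred on noe_true * i_ref; both heights
    get Gaussian noise of width noise_fraction * i_ref and errors of
    max(noise_fraction*i_ref, 2% of the height).
    """
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be >= 0")
    rng = substream(seed, f"noe:{residue_id}")
    sigma = noise_fraction * abs(i_ref)
    h_sat = noe_true * i_ref + (rng.normal(0.0, sigma) if sigma else 0.0)
    h_ref = i_ref + (rng.normal(0.0, sigma) if sigma else 0.0)
    err = max(sigma, 1e-12 * max(abs(i_ref), 1.0))
    sat = Peak(residue_id, atom_label, 0.0, 0.0, h_sat,
               max(err, 0.02 * abs(h_sat)))
    ref = Peak(residue_id, atom_label, 0.0, 0.0, h_ref,
               max(err, 0.02 * abs(h_ref)))
    return sat, ref


def gen_dispersion_dataset(params: ExchangeParams,
                           settings_by_probe: Sequence[tuple[str, CPMGSettings]],
                           noise_fraction: float, seed: int,
                           i0: float = 1.0) -> list[dict]:
    """Synthetic CPMG intensity tables for a set of probes and fields.

    For each (probe, settings) pair the model R2,eff is evaluated and
    intensities are drawn as
    i0 * exp(-R2eff(nu) * T_relax) * (1 + Normal(0, noise_fraction));
    replicate nu points get independent noise.  Returns one record per
    curve with the nu grid, intensities and reference intensity.
    """
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be >= 0")
    out = []
    for probe_id, settings in settings_by_probe:
        dwc = params.dw_C.get(probe_id, 0.0)
        dwh = params.dw_H.get(probe_id, 0.0)
        r20 = params.r2_0[(probe_id, settings.field_1H)]
        model = _dsp.model_curve(params.kex, params.p_b, dwc, dwh, r20,
                                 settings)
        rng = substream(seed, f"cpmg:{probe_id}:{settings.coherence}:"
                              f"{settings.field_1H:g}")
        clean = i0 * np.exp(-model * settings.T_relax)
        noisy = clean * (1.0 + rng.normal(0.0, noise_fraction, len(clean))) \
            if noise_fraction > 0 else clean
        out.append({
            "probe_id": probe_id,
            "settings": settings,
            "nu_cpmg": settings.nu_cpmg.copy(),
            "intensities": noisy,
            "reference_intensity": i0,
            "model_r2eff": model,
        })
    return out


def _lorentz2d_grid(x: np.ndarray, y: np.ndarray, x0: float, y0: float,
                    wx: float, wy: float, volume: float) -> np.ndarray:
    X, Y = np.meshgrid(x, y)
    amp = volume / (np.pi ** 2 * wx * wy)
    return amp / ((1.0 + ((X - x0) / wx) ** 2) * (1.0 + ((Y - y0) / wy) ** 2))


def gen_peak_cluster(positions: Sequence[tuple[float, float]],
                     linewidths: Sequence[tuple[float, float]],
                     populations: Sequence[float],
                     x_ppm: np.ndarray, y_ppm: np.ndarray,
                     noise_fraction: float, seed: int,
                     total_volume: float = 1.0
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Overlapping 2D Lorentzian resonance cluster on a shift grid.

    Component volumes are proportional to the requested fractional
    populations; Gaussian grid noise has width noise_fraction times the
    maximum clean intensity.  Returns (x_ppm, y_ppm, grid).
    """
    pops = np.asarray(populations, dtype=float)
    if abs(pops.sum() - 1.0) > 1e-6:
        raise ValueError("populations must sum to 1")
    if len(positions) != len(pops) or len(linewidths) != len(pops):
        raise ValueError("positions, linewidths and populations must align")
    x_ppm = np.asarray(x_ppm, dtype=float)
    y_ppm = np.asarray(y_ppm, dtype=float)
    grid = np.zeros((len(y_ppm), len(x_ppm)))
    for (px, py), (wx, wy), p in zip(positions, linewidths, pops):
        grid += _lorentz2d_grid(x_ppm, y_ppm, px, py, wx, wy, p * total_volume)
    if noise_fraction > 0:
        rng = substream(seed, "cluster")
        grid = grid + rng.normal(0.0, noise_fraction * grid.max(), grid.shape)
    return x_ppm, y_ppm, grid


def gen_csp_tables(n_residues: int, perturbed: dict[int, tuple[float, float]],
                   noise_ppm: float, seed: int, nucleus: str = "N"
                   ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Paired-condition shift tables with a known perturbed residue set.

    ``perturbed`` maps residue id -> (effect_H, effect_X) in ppm, added
    to condition 2; all residues in both conditions get Gaussian shift
    noise of width ``noise_ppm``.  Returns the two tables plus the
    ground truth (perturbed ids and effects).
    """
    if noise_ppm < 0:
        raise ValueError("noise_ppm must be >= 0")
    rng = substream(seed, "csp")
    residues = np.arange(1, n_residues + 1)
    base_h = 7.5 + rng.uniform(0.0, 2.0, n_residues)
    base_x = (118.0 if nucleus == "N" else 20.0) + rng.uniform(0.0, 10.0,
                                                               n_residues)
    atom = "N-H" if nucleus == "N" else "C-H"

    def noisy(values: np.ndarray) -> np.ndarray:
        return values + (rng.normal(0.0, noise_ppm, values.shape)
                         if noise_ppm > 0 else 0.0)

    eff_h = np.array([perturbed.get(r, (0.0, 0.0))[0] for r in residues])
    eff_x = np.array([perturbed.get(r, (0.0, 0.0))[1] for r in residues])
    cond1 = pd.DataFrame({"residue": residues, "atom": atom,
                          "shift_h": noisy(base_h), "shift_x": noisy(base_x)})
    cond2 = pd.DataFrame({"residue": residues, "atom": atom,
                          "shift_h": noisy(base_h + eff_h),
                          "shift_x": noisy(base_x + eff_x)})
    truth = {"perturbed": sorted(perturbed), "effects": dict(perturbed),
             "noise_ppm": noise_ppm, "nucleus": nucleus}
    return cond1, cond2, truth


@dataclass(frozen=True)
class SyntheticPreset:
    """Immutable named bundle of generating parameters.

    ``assumed`` lists the parameter names that are package assumptions
    rather than literature-printed values.
    """

    name: str
    kind: str
    params: dict
    assumed: tuple[str, ...] = ()
    noise_fraction: float = 0.02
    version: str = GENERATOR_VERSION


PRESETS: dict[str, SyntheticPreset] = {
    # Na+-saturated selectivity filter, pairwise 13C MQ fit: kex = 390 1/s.
    # The V64-like probe reproduces the observed endpoint Rex of ~15 s^-1
    # at 800 MHz and the V59-like probe a weaker ~7 s^-1 dispersion.
    "nak_na_sf": SyntheticPreset(
        name="nak_na_sf", kind="dispersion",
        params={
            "kex": 390.0, "p_b": 0.05,
            "probes": {"V64-Cg2": {"dw_C": 1.0, "dw_H": 0.02},
                       "V59-Cg2": {"dw_C": 0.3, "dw_H": 0.01}},
            "coherence": "MQ_13C",
            "fields": (800.0, 600.0),
            "T_relax": 0.030,
            "nu_cpmg": NU_CPMG_NA_MQ,
            "r2_0": 20.0,
        },
        assumed=("p_b", "dw_C", "dw_H", "r2_0"),
    ),
    # Na+ pairing of one 13C MQ probe with one 1H SQ probe: kex = 356 1/s.
    "nak_na_sf_sq": SyntheticPreset(
        name="nak_na_sf_sq", kind="dispersion",
        params={
            "kex": 356.0, "p_b": 0.05,
            "probes": {"V59-Cg2": {"dw_C": 0.35, "dw_H": 0.01,
                                   "coherence": "MQ_13C",
                                   "fields": (800.0, 600.0),
                                   "T_relax": 0.030,
                                   "nu_cpmg": NU_CPMG_NA_MQ},
                       "L48-Hd1": {"dw_C": 0.0, "dw_H": 0.15,
                                   "coherence": "SQ_1H",
                                   "fields": (900.0, 600.0),
                                   "T_relax": 0.020,
                                   "nu_cpmg": NU_CPMG_NA_SQ}},
            "r2_0": 20.0,
        },
        assumed=("p_b", "dw_C", "dw_H", "r2_0"),
    ),
    # L48a methyl cluster in K+: major state 86%, two minors at 7% each.
    "L48a_K": SyntheticPreset(
        name="L48a_K", kind="cluster",
        params={
            "populations": (0.86, 0.07, 0.07),
            "positions": ((0.30, 23.0), (0.40, 23.35), (0.20, 22.65)),
            "linewidths": ((0.025, 0.12),) * 3,
            "x_range": (0.0, 0.6, 96),
            "y_range": (21.8, 24.4, 96),
        },
        assumed=("positions", "linewidths"),
    ),
    # L48a in Na+: populations redistribute to 47/37/16.
    "L48a_Na": SyntheticPreset(
        name="L48a_Na", kind="cluster",
        params={
            "populations": (0.47, 0.37, 0.16),
            "positions": ((0.20, 22.65), (0.30, 23.0), (0.40, 23.35)),
            "linewidths": ((0.025, 0.12),) * 3,
            "x_range": (0.0, 0.6, 96),
            "y_range": (21.8, 24.4, 96),
        },
        assumed=("positions", "linewidths"),
    ),
    # N68 amide NOE in K+: 0.43.
    "N68_K": SyntheticPreset(
        name="N68_K", kind="noe",
        params={"noe_true": 0.43, "i_ref": 100.0, "residue_id": 68},
        assumed=("i_ref",),
    ),
}


def _dispersion_layout(preset: SyntheticPreset
                       ) -> tuple[ExchangeParams, list[tuple[str, CPMGSettings]]]:
    p = preset.params
    dw_c, dw_h, r2_0 = {}, {}, {}
    layout: list[tuple[str, CPMGSettings]] = []
    for probe_id, probe_cfg in p["probes"].items():
        dw_c[probe_id] = probe_cfg.get("dw_C", 0.0)
        dw_h[probe_id] = probe_cfg.get("dw_H", 0.0)
        coherence = probe_cfg.get("coherence", p.get("coherence"))
        fields = probe_cfg.get("fields", p.get("fields"))
        t_relax = probe_cfg.get("T_relax", p.get("T_relax"))
        nu = probe_cfg.get("nu_cpmg", p.get("nu_cpmg"))
        for field_1h in fields:
            r2_0[(probe_id, field_1h)] = p["r2_0"]
            layout.append((probe_id, CPMGSettings(
                T_relax=t_relax, nu_cpmg=np.asarray(nu, dtype=float),
                field_1H=field_1h, coherence=coherence)))
    params = ExchangeParams(kex=p["kex"], p_b=p["p_b"], dw_C=dw_c,
                            dw_H=dw_h, r2_0=r2_0)
    return params, layout


def preset_dispersion_curves(name: str, seed: int,
                             noise_fraction: Optional[float] = None
                             ) -> tuple[ExchangeParams, list[DispersionCurve]]:
    """Generate replicate-pooled dispersion curves for a named preset."""
    preset = PRESETS[name]
    if preset.kind != "dispersion":
        raise ValueError(f"{name!r} is not a dispersion preset")
    nf = preset.noise_fraction if noise_fraction is None else noise_fraction
    params, layout = _dispersion_layout(preset)
    tables = gen_dispersion_dataset(params, layout, nf, seed)
    curves = [_dsp.r2eff_from_intensities(t["intensities"],
                                          t["reference_intensity"],
                                          t["settings"], t["probe_id"])
              for t in tables]
    return params, curves


def preset_cluster(name: str, seed: int,
                   noise_fraction: Optional[float] = None
                   ) -> tuple[SyntheticPreset, np.ndarray, np.ndarray, np.ndarray]:
    """Generate the 2D intensity grid for a named cluster preset."""
    preset = PRESETS[name]
    if preset.kind != "cluster":
        raise ValueError(f"{name!r} is not a cluster preset")
    nf = preset.noise_fraction if noise_fraction is None else noise_fraction
    p = preset.params
    x = np.linspace(*p["x_range"][:2], p["x_range"][2])
    y = np.linspace(*p["y_range"][:2], p["y_range"][2])
    x, y, grid = gen_peak_cluster(p["positions"], p["linewidths"],
                                  p["populations"], x, y, nf, seed)
    return preset, x, y, grid


def preset_noe_pair(name: str, seed: int,
                    noise_fraction: Optional[float] = None
                    ) -> tuple[SyntheticPreset, Peak, Peak]:
    """Generate the saturated/reference pair for a named NOE preset."""
    preset = PRESETS[name]
    if preset.kind != "noe":
        raise ValueError(f"{name!r} is not an NOE preset")
    nf = preset.noise_fraction if noise_fraction is None else noise_fraction
    p = preset.params
    sat, ref = gen_noe_pair(p["noe_true"], p["i_ref"], nf, seed,
                            residue_id=p["residue_id"])
    return preset, sat, ref
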