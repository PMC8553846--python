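"""Readers and writers for peak lists, series tables, shift tables and
per-residue attribute files.

Supported inputs are Sparky ``.list`` peak lists (whitespace-aligned,
``G67N-H``-style assignment labels), headered TSV/CSV tables (UTF-8,
``.`` decimal separator) and a YAML run configuration.  Outputs are CSV
result tables and Chimera-style attribute files for structure coloring.

Residue numbering is taken verbatim from the input files; no
renumbering is ever applied.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .types import (
    DEFAULT_ERROR_FLOOR,
    CSPWeights,
    Peak,
    PeakTable,
    PipelineConfig,
    RelaxSeries,
)

__all__ = [
    "apply_error_floor",
    "read_peak_list",
    "read_series_table",
    "read_shift_table",
    "write_residue_attributes",
    "read_residue_attributes",
    "load_config",
]

PathLike = Union[str, Path]


class PeakListParseError(ValueError):
    """Raised for malformed peak-list lines; carries the line number."""


def apply_error_floor(height: float, error: Optional[float] = None,
                      floor: float = DEFAULT_ERROR_FLOOR) -> float:
    """Return the peak-height error after applying the fractional floor.

    If no explicit error is given, or the given error is smaller than
    ``floor * |height|``, the floor value is assumed instead.
    """
    floor_err = floor * abs(height)
    if error is None or error < floor_err:
        return floor_err
    return error


# Sparky assignment labels: one-letter residue code, number, atom names,
# e.g. "G67N-H", "V64CG2-HG2", "?-?" for unassigned.
_SPARKY_ASSIGN = re.compile(r"^([A-Za-z])(\d+)([A-Za-z0-9'\-]+)$")


def _parse_sparky_assignment(label: str, lineno: int) -> tuple[int, str]:
    m = _SPARKY_ASSIGN.match(label)
    if m is None:
        raise PeakListParseError(
            f"line {lineno}: cannot parse assignment label {label!r}"
        )
    return int(m.group(2)), m.group(3)


def read_peak_list(path: PathLike, dialect: str = "tsv",
                   condition_label: str = "", field_1H: Optional[float] = None,
                   error_floor: float = DEFAULT_ERROR_FLOOR) -> PeakTable:
    """Read a peak list into a :class:`PeakTable`.

    ``dialect="sparky"`` expects whitespace-aligned columns
    ``Assignment w1 w2 Height [Height_error]``; ``dialect="tsv"``
    expects a headered table with columns ``residue``, ``atom``, ``w1``,
    ``w2``, ``height`` and optionally ``height_error``.  The fractional
    error floor is applied whenever an explicit error is absent or
    smaller.
    """
    path = Path(path)
    if dialect == "sparky":
        peaks = _read_sparky(path, error_floor)
    elif dialect == "tsv":
        peaks = _read_peak_tsv(path, error_floor)
    else:
        raise ValueError(f"unsupported peak-list dialect {dialect!r}")
    return PeakTable(condition_label=condition_label, peaks=peaks, field_1H=field_1H)


def _read_sparky(path: Path, error_floor: float) -> list[Peak]:
    peaks: list[Peak] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.lower().startswith("assignment"):
                continue  # Sparky header row
            fields = line.split()
            if len(fields) < 4:
                raise PeakListParseError(
                    f"line {lineno}: expected >= 4 columns, got {len(fields)}"
                )
            residue_id, atom = _parse_sparky_assignment(fields[0], lineno)
            try:
                w1, w2, height = (float(x) for x in fields[1:4])
                error = float(fields[4]) if len(fields) > 4 else None
            except ValueError as exc:
                raise PeakListParseError(f"line {lineno}: {exc}") from None
            peaks.append(Peak(residue_id, atom, w1, w2, height,
                              apply_error_floor(height, error, error_floor)))
    return peaks


def _read_peak_tsv(path: Path, error_floor: float) -> list[Peak]:
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"residue", "atom", "w1", "w2", "height"}
    missing = required - set(df.columns)
    if missing:
        raise PeakListParseError(f"missing columns: {sorted(missing)}")
    peaks: list[Peak] = []
    for i, row in df.iterrows():
        try:
            height = float(row["height"])
            error = float(row["height_error"]) if "height_error" in df.columns and \
                pd.notna(row.get("height_error")) else None
        except (TypeError, ValueError) as exc:
            raise PeakListParseError(f"line {i + 2}: {exc}") from None
        peaks.append(Peak(int(row["residue"]), str(row["atom"]).strip(),
                          float(row["w1"]), float(row["w2"]), height,
                          apply_error_floor(height, error, error_floor)))
    return peaks


def read_series_table(path: PathLike, experiment: str = "R1",
                      error_fraction: float = DEFAULT_ERROR_FLOOR
                      ) -> list[RelaxSeries]:
    """Read a residue x delay intensity table into RelaxSeries objects.

    The first column is the residue number; every remaining column
    header is a relaxation delay in seconds.  Duplicate delay columns
    (replicates) are retained as separate points.  Missing cells are
    allowed and simply absent from the series.  A residue with fewer
    than two usable points is returned with its data but is flagged
    unfittable (``series.fittable``), not treated as a fatal error.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    cols = [c.strip() for c in header.rstrip("\n").split(sep)]
    try:
        delays = np.array([float(c) for c in cols[1:]])
    except ValueError as exc:
        raise ValueError(f"series table delays must be numeric seconds: {exc}") from None
    df = pd.read_csv(path, sep=sep, skiprows=1, header=None)
    out: list[RelaxSeries] = []
    for _, row in df.iterrows():
        residue = int(row.iloc[0])
        vals = row.iloc[1:].to_numpy(dtype=float)
        mask = np.isfinite(vals)
        inten = vals[mask]
        errs = np.maximum(error_fraction * np.abs(inten), 1e-12)
        out.append(RelaxSeries(residue, experiment, delays[mask], inten, errs))
    return out


def read_shift_table(path: PathLike) -> pd.DataFrame:
    """Read a per-residue chemical-shift table (one row per residue/atom).

    Expected columns: ``residue``, ``atom``, ``shift_H`` (ppm) and
    ``shift_X`` (ppm, the 15N or 13C partner).  An optional ``height``
    column marks the major state when a residue has several rows.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"residue", "atom", "shift_h", "shift_x"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"shift table missing columns: {sorted(missing)}")
    df["residue"] = df["residue"].astype(int)
    df["atom"] = df["atom"].astype(str).str.strip()
    return df


def write_residue_attributes(values: dict[int, float], path: PathLike,
                             attribute_name: str) -> None:
    """Write a Chimera-style per-residue attribute file.

    One ``\t:<residue>\t<value>`` line per entry, ordered by residue
    number.  Residues absent from ``values`` get no line: absence
    encodes "data unavailable" for structure coloring.
    """
    if not values:
        raise ValueError("values must be non-empty")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"attribute: {attribute_name}\n")
        fh.write("match mode: 1-to-1\n")
        fh.write("recipient: residues\n")
        for residue in sorted(values):
            fh.write(f"\t:{residue}\t{values[residue]!r}\n")


def read_residue_attributes(path: PathLike) -> dict[int, float]:
    """Parse an attribute file written by :func:`write_residue_attributes`."""
    out: dict[int, float] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("\t:"):
                continue
            residue_s, value_s = line.strip().split("\t")
            out[int(residue_s.lstrip(":"))] = float(value_s)
    return out


def load_config(path: PathLike) -> PipelineConfig:
    """Load a YAML run configuration into a validated PipelineConfig."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    weights = CSPWeights(**raw.pop("weights", {}))
    known = {"mc_replicates", "error_floor", "threshold_sigma_factor",
             "trim_fraction", "seed"}
    kwargs = {k: raw.pop(k) for k in list(raw) if k in known}
    experiments = raw.pop("experiments", {})
    if raw:
        raise ValueError(f"unknown config keys: {sorted(raw)}")
    return PipelineConfig(weights=weights, experiments=experiments, **kwargs)
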