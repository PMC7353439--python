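"""Delimited-text I/O and report serialization.

File formats are deliberately plain: CSV with a header row, times in
hours (or seconds via ``time_unit="s"``), concentrations in mg/L, CFU
counts in CFU/mL.  Reports are JSON objects or CSV tables with fixed
column order.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    DissolutionSeries,
    HOUR,
    InvalidInputError,
    LITRE,
    MG_PER_L,
    ParticleSpec,
)
from .growth import GrowthCurve
from .stepselect import StepDeterminationResult

__all__ = [
    "read_dissolution_csv",
    "write_dissolution_csv",
    "read_growth_csv",
    "write_growth_csv",
    "step_report_frame",
    "write_json_report",
]

_TIME_FACTORS = {"h": HOUR, "s": 1.0}


def _require_columns(df: pd.DataFrame, cols: tuple, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        raise InvalidInputError(f"{path}: no data rows")


def read_dissolution_csv(
    path,
    volume_L: float,
    initial_copper_mass_g: float,
    time_unit: str = "h",
    label: str = "",
) -> DissolutionSeries:
    """Read a two-column dissolution CSV (time, conc_mg_L).

    The time column is ``time_h`` (or ``time_s`` with ``time_unit="s"``);
    concentration is ``conc_mg_L``.  Malformed numeric entries are
    reported with their line number.
    """
    if time_unit not in _TIME_FACTORS:
        raise InvalidInputError("time_unit must be 'h' or 's'")
    tcol = f"time_{time_unit}"
    df = pd.read_csv(path)
    _require_columns(df, (tcol, "conc_mg_L"), path)
    for col in (tcol, "conc_mg_L"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(np.flatnonzero(bad)[0]) + 2  # 1-based + header
            raise InvalidInputError(f"{path}: non-numeric value in column "
                                    f"{col!r} at line {line}")
    times = pd.to_numeric(df[tcol]).to_numpy(float) * _TIME_FACTORS[time_unit]
    conc = pd.to_numeric(df["conc_mg_L"]).to_numpy(float) * MG_PER_L
    return DissolutionSeries(
        times=times,
        concentration=conc,
        volume_V=volume_L * LITRE,
        initial_copper_mass=initial_copper_mass_g * 1e-3,
        label=label or Path(str(path)).stem,
    )


def write_dissolution_csv(series: DissolutionSeries, path) -> None:
    pd.DataFrame({
        "time_h": series.times_h,
        "conc_mg_L": series.concentration_mg_L,
    }).to_csv(path, index=False)


def read_growth_csv(path) -> dict[str, GrowthCurve]:
    """Read CFU curves (time_h, cfu_per_ml[, label]) into a dict by label."""
    df = pd.read_csv(path)
    _require_columns(df, ("time_h", "cfu_per_ml"), path)
    if "label" not in df.columns:
        df["label"] = Path(str(path)).stem
    out = {}
    for label, grp in df.groupby("label", sort=False):
        out[str(label)] = GrowthCurve(
            times_h=grp["time_h"].to_numpy(float),
            cfu=grp["cfu_per_ml"].to_numpy(float),
            label=str(label),
        )
    return out


def write_growth_csv(curves, path) -> None:
    frames = []
    for c in curves:
        frames.append(pd.DataFrame({"time_h": c.times_h, "cfu_per_ml": c.cfu,
                                    "label": c.label}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def step_report_frame(result: StepDeterminationResult, sample: str = "") -> pd.DataFrame:
    """Tabular step-determination report (one row per candidate regime)."""
    rows = result.to_rows()
    df = pd.DataFrame(rows, columns=["step", "slope_inv_tau_per_s",
                                     "adjusted_R2", "standard_error",
                                     "n_points", "selected"])
    if sample:
        df.insert(0, "sample", sample)
    return df


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    if hasattr(obj, "value"):  # enums
        return obj.value
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=_jsonable) + "\n")


def particle_from_config(cfg: dict) -> ParticleSpec:
    """Build a ParticleSpec from a config mapping (radius in nm, density kg/m^3)."""
    try:
        return ParticleSpec(
            species_label=str(cfg.get("label", "sample")),
            radius_R=float(cfg["radius_nm"]) * 1e-9,
            density_rho=float(cfg["density_kg_m3"]),
            copper_mass_fraction=float(cfg.get("copper_mass_fraction", 1.0)),
        )
    except KeyError as e:
        raise InvalidInputError(f"particle config missing key {e}") from e
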