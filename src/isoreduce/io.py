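"""File readers and writers: run-sequence CSV, result CSV, TOML registries.

Run files are comma-delimited UTF-8 with dot decimals and plain permil
numbers.  Run-level metadata (reactor, equilibration water, autosampler,
date, seed) travels in ``# key = value`` comment lines ahead of the
header, so a run is a single self-contained file.  Empty delta cells mean
the channel is absent (e.g. no CO from a chromium reactor).
"""

from __future__ import annotations

import tomllib
from pathlib import Path
from typing import Iterable

import pandas as pd

from .core import (
    AnalysisRecord,
    EquilibrationWater,
    ReferenceMaterial,
    RunSequence,
    SchemaError,
    results_frame,
)

RUN_COLUMNS = ["position", "material_id", "role", "d2H_raw", "d13C_raw",
               "d18O_raw", "area_H2", "area_CO", "mass_mg", "time_min"]
_REQUIRED_RUN_COLUMNS = RUN_COLUMNS[:9]

_DELTA_COLS = {"d2H_raw": "d2H", "d13C_raw": "d13C", "d18O_raw": "d18O"}
_AREA_COLS = {"area_H2": "H2", "area_CO": "CO"}

_META_KEYS = ("reactor", "equilibration_water_id", "autosampler", "run_date", "seed")


def write_run_csv(path, run: RunSequence) -> None:
    """Write a run sequence with its metadata as comment lines."""
    path = Path(path)
    lines = []
    for key in _META_KEYS:
        val = getattr(run, key)
        if val is not None:
            lines.append(f"# {key} = {val}")
    lines.append(",".join(RUN_COLUMNS))
    for r in run.records:
        row = [str(r.position), r.material_id, r.role]
        for col, iso in _DELTA_COLS.items():
            row.append(repr(r.delta_raw[iso]) if iso in r.delta_raw else "")
        for col, gas in _AREA_COLS.items():
            row.append(repr(r.peak_area[gas]) if gas in r.peak_area else "")
        row.append("" if r.mass_mg is None else repr(r.mass_mg))
        row.append("" if r.time_min is None else repr(r.time_min))
        lines.append(",".join(row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_run_csv(path) -> RunSequence:
    """Read a run sequence written by :func:`write_run_csv`.

    Malformed rows are reported with their 1-based file line number; a
    missing required column raises a :class:`~isoreduce.core.SchemaError`.
    """
    path = Path(path)
    meta = {}
    header_line = 0
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if stripped.startswith("#"):
                if "=" in stripped:
                    key, _, val = stripped.lstrip("# ").partition("=")
                    meta[key.strip()] = val.strip()
                continue
            header_line = lineno
            break
    df = pd.read_csv(path, comment="#", dtype={"material_id": str, "role": str},
                     float_precision="round_trip")
    missing = [c for c in _REQUIRED_RUN_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")

    records = []
    for offset, row in enumerate(df.itertuples(index=False)):
        lineno = header_line + 1 + offset
        try:
            deltas = {
                iso: float(getattr(row, col))
                for col, iso in _DELTA_COLS.items()
                if col in df.columns and pd.notna(getattr(row, col))
            }
            areas = {
                gas: float(getattr(row, col))
                for col, gas in _AREA_COLS.items()
                if col in df.columns and pd.notna(getattr(row, col))
            }
            records.append(
                AnalysisRecord(
                    position=int(row.position),
                    material_id=str(row.material_id),
                    role=str(row.role),
                    delta_raw=deltas,
                    peak_area=areas,
                    mass_mg=float(row.mass_mg) if pd.notna(row.mass_mg) else None,
                    time_min=float(row.time_min)
                    if "time_min" in df.columns and pd.notna(row.time_min) else None,
                )
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}:{lineno}: malformed row ({exc})") from exc

    seed = meta.get("seed")
    return RunSequence(
        records=records,
        reactor=meta.get("reactor", "glassy_carbon"),
        equilibration_water_id=meta.get("equilibration_water_id"),
        autosampler=meta.get("autosampler", "zero_blank"),
        run_date=meta.get("run_date"),
        seed=int(seed) if seed is not None else None,
    )


def write_results(path, results: Iterable) -> None:
    """Write reduced results as CSV (one row per analysis)."""
    results_frame(results).to_csv(path, index=False, float_format="%.6f")


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"material_id": str, "role": str})
    if "flags" in df.columns:
        df["flags"] = df["flags"].fillna("")
    return df


# ---------------------------------------------------------------------------
# Registries
# ---------------------------------------------------------------------------

def read_materials(path) -> dict:
    """Read a reference-material registry from TOML ([[material]] tables)."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    if "material" not in data:
        raise SchemaError(f"{path}: no [[material]] entries")
    out = {}
    for entry in data["material"]:
        try:
            certified = {
                iso: float(entry[key])
                for key, iso in (("d2H", "d2H"), ("d13C", "d13C"), ("d18O", "d18O"))
                if key in entry
            }
            mat = ReferenceMaterial(
                id=entry["id"],
                material_class=entry.get("material_class", "other"),
                certified=certified,
                x_e=entry.get("x_e"),
                n_content_pct=float(entry.get("n_content_pct", 0.0)),
                s_content_pct=float(entry.get("s_content_pct", 0.0)),
                exchanges_h=bool(entry.get("exchanges_h", True)),
            )
        except KeyError as exc:
            raise SchemaError(f"{path}: material entry missing {exc}") from exc
        out[mat.id] = mat
    return out


def write_materials(path, materials: dict) -> None:
    lines = []
    for mat in materials.values():
        lines.append("[[material]]")
        lines.append(f'id = "{mat.id}"')
        lines.append(f'material_class = "{mat.material_class}"')
        for iso in ("d2H", "d13C", "d18O"):
            if iso in mat.certified:
                lines.append(f"{iso} = {mat.certified[iso]!r}")
        if mat.x_e is not None:
            lines.append(f"x_e = {mat.x_e!r}")
        lines.append(f"n_content_pct = {mat.n_content_pct!r}")
        lines.append(f"s_content_pct = {mat.s_content_pct!r}")
        lines.append(f"exchanges_h = {'true' if mat.exchanges_h else 'false'}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


def read_waters(path) -> dict:
    """Read an equilibration-water registry from TOML ([[water]] tables)."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    if "water" not in data:
        raise SchemaError(f"{path}: no [[water]] entries")
    out = {}
    for entry in data["water"]:
        try:
            w = EquilibrationWater(
                id=entry["id"],
                delta2H=float(entry["delta2H"]),
                uncertainty=float(entry.get("uncertainty", 0.0)),
            )
        except KeyError as exc:
            raise SchemaError(f"{path}: water entry missing {exc}") from exc
        out[w.id] = w
    return out


def write_waters(path, waters: dict) -> None:
    lines = []
    for w in waters.values():
        lines.append("[[water]]")
        lines.append(f'id = "{w.id}"')
        lines.append(f"delta2H = {w.delta2H!r}")
        lines.append(f"uncertainty = {w.uncertainty!r}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")
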