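"""File I/O: spectra import, solution/validation export, device configs.

CSV dialect for spectra: comma-separated, dot decimal, UTF-8, one header
row; first column is wavelength in nm, each remaining column one primary
(or one standard-observer function).  Spreadsheets (.xlsx) follow the same
column layout.  All JSON schemas carry a ``schema_version`` field.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .device import Device, Primary
from .observer import PHOTORECEPTORS, DensityTemplate, Observer
from .solver import StimulusSolution
from .spectra import (
    CANONICAL_GRID,
    Spectrum,
    UNIT_OPTICAL_DENSITY,
    UNIT_SENSITIVITY,
    WavelengthGrid,
    resample,
)
from .validation import ValidationReport

__all__ = [
    "SCHEMA_VERSION",
    "export_solution",
    "load_config",
    "load_observer_bundle",
    "read_solution",
    "read_spectra",
    "save_config",
    "write_observer_bundle",
    "write_spectra",
]

logger = logging.getLogger("substim")

SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# Spectra import/export
# ---------------------------------------------------------------------------


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path)
    return pd.read_csv(path)


def read_spectra(
    path: str | Path, grid: WavelengthGrid = CANONICAL_GRID
) -> list[tuple[str, Spectrum]]:
    """Import primary emission spectra from a CSV or spreadsheet.

    The first column is wavelength (nm, strictly increasing); each further
    column is one primary, named by its header.  Spectra are resampled onto
    the canonical grid; column order is preserved (it defines primary order).

    Raises
    ------
    ValueError
        On fewer than 3 or more than 5 value columns, non-monotone
        wavelengths, or negative/non-finite values.
    """
    table = _read_table(path)
    if table.shape[1] < 2:
        raise ValueError(f"{path}: expected a wavelength column plus primary columns")
    wl = table.iloc[:, 0].to_numpy(dtype=float)
    if np.any(~np.isfinite(wl)) or np.any(np.diff(wl) <= 0):
        raise ValueError(f"{path}: wavelengths must be finite and strictly increasing")
    n_cols = table.shape[1] - 1
    if not 3 <= n_cols <= 5:
        raise ValueError(
            f"{path}: found {n_cols} primary column(s); a device needs between "
            "3 and 5 primaries"
        )
    out: list[tuple[str, Spectrum]] = []
    src_grid = _grid_from_wavelengths(wl)
    for name in table.columns[1:]:
        values = table[name].to_numpy(dtype=float)
        if np.any(~np.isfinite(values)) or np.any(values < 0):
            raise ValueError(f"{path}: column {name!r} has negative or non-finite values")
        if src_grid is not None:
            spectrum = Spectrum(src_grid, values)
        else:
            # non-uniform source: interpolate directly onto the target grid
            spectrum = Spectrum(
                grid, np.interp(grid.wavelengths, wl, values, left=0.0, right=0.0)
            )
        out.append((str(name), resample(spectrum, grid)))
    return out


def _grid_from_wavelengths(wl: np.ndarray) -> WavelengthGrid | None:
    steps = np.diff(wl)
    if np.allclose(steps, steps[0], rtol=0, atol=1e-9):
        return WavelengthGrid(float(wl[0]), float(wl[-1]), float(steps[0]))
    return None


def write_spectra(path: str | Path, spectra: list[tuple[str, Spectrum]]) -> None:
    """Write named spectra in the CSV dialect (wavelength + one column each)."""
    grid = spectra[0][1].grid
    data = {"wavelength": grid.wavelengths}
    for name, spectrum in spectra:
        if spectrum.grid != grid:
            raise ValueError("all exported spectra must share one grid")
        data[name] = spectrum.values
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Solution / validation export
# ---------------------------------------------------------------------------


def _solution_dict(solution: StimulusSolution) -> dict:
    return {
        "primary_names": list(solution.primary_names),
        "primary_contrasts": [float(v) for v in solution.primary_contrasts],
        "scale_applied": float(solution.scale_applied),
        "min_luminance": [float(v) for v in solution.min_luminance],
        "max_luminance": [float(v) for v in solution.max_luminance],
        "feasible_primary": list(solution.feasible_primary),
        "feasible": bool(solution.feasible),
        "warnings": list(solution.warnings),
    }


def _report_dict(report: ValidationReport) -> dict:
    return {
        "achieved": {p: float(v) for p, v in report.achieved.items()},
        "observer_params": dict(report.observer_params),
        "contribution": [[float(v) for v in row] for row in report.contribution],
        "photoreceptors": list(report.photoreceptors),
        "primaries": list(report.primaries),
        "controlled": list(report.controlled),
    }


def export_solution(
    solution: StimulusSolution,
    path: str | Path,
    report: ValidationReport | None = None,
    fmt: str | None = None,
) -> None:
    """Export a solved stimulus (and optional validation) as JSON or XLSX.

    The JSON form round-trips bitwise through :func:`read_solution`; the
    spreadsheet mirrors the on-screen result table, one row per primary.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "json":
        payload = {
            "schema_version": SCHEMA_VERSION,
            "solution": _solution_dict(solution),
            "validation": _report_dict(report) if report is not None else None,
        }
        path.write_text(json.dumps(payload, indent=2))
    elif fmt == "xlsx":
        with pd.ExcelWriter(path, engine="openpyxl") as writer:
            solution.to_frame().to_excel(writer, sheet_name="solution", index=False)
            if report is not None:
                report.to_frame().to_excel(writer, sheet_name="validation", index=False)
                report.contribution_frame().to_excel(writer, sheet_name="contribution")
    else:
        raise ValueError(f"unknown export format {fmt!r}; use 'json' or 'xlsx'")


def read_solution(path: str | Path) -> tuple[StimulusSolution, ValidationReport | None]:
    """Read back a JSON solution export."""
    payload = json.loads(Path(path).read_text())
    _check_schema_version(payload, path)
    s = payload["solution"]
    solution = StimulusSolution(
        primary_names=tuple(s["primary_names"]),
        primary_contrasts=np.array(s["primary_contrasts"]),
        scale_applied=s["scale_applied"],
        min_luminance=np.array(s["min_luminance"]),
        max_luminance=np.array(s["max_luminance"]),
        feasible_primary=tuple(bool(v) for v in s["feasible_primary"]),
        feasible=bool(s["feasible"]),
        warnings=tuple(s["warnings"]),
    )
    report = None
    if payload.get("validation") is not None:
        r = payload["validation"]
        report = ValidationReport(
            achieved={p: float(v) for p, v in r["achieved"].items()},
            observer_params=r["observer_params"],
            contribution=np.array(r["contribution"]),
            photoreceptors=tuple(r["photoreceptors"]),
            primaries=tuple(r["primaries"]),
            controlled=tuple(r["controlled"]),
        )
    return solution, report


def _check_schema_version(payload: dict, path: str | Path) -> None:
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"{path}: schema version {version!r} is not supported "
            f"(this build reads version {SCHEMA_VERSION})"
        )


# ---------------------------------------------------------------------------
# Device configuration ("bookmark") persistence
# ---------------------------------------------------------------------------


def _grid_dict(grid: WavelengthGrid) -> dict:
    return {"start": grid.start, "stop": grid.stop, "step": grid.step}


def save_config(device: Device, path: str | Path) -> None:
    """Persist a device (names, luminances, ranges, embedded spectra) as JSON."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "grid": _grid_dict(device.vlambda.grid),
        "vlambda": [float(v) for v in device.vlambda.values],
        "primaries": [
            {
                "name": p.name,
                "mean_luminance": float(p.mean_luminance),
                "lum_range": [float(p.lum_range[0]), float(p.lum_range[1])],
                "emission": [float(v) for v in p.emission.values],
            }
            for p in device.primaries
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_config(path: str | Path) -> Device:
    """Load a device config; validates luminances against their own ranges.

    A missing ``lum_range`` gets the default [0, 2·mean] with a logged
    warning; a mean luminance outside its stated range is rejected.
    """
    payload = json.loads(Path(path).read_text())
    _check_schema_version(payload, path)
    g = payload["grid"]
    grid = WavelengthGrid(g["start"], g["stop"], g["step"])
    vlambda = Spectrum(grid, np.array(payload["vlambda"]), UNIT_SENSITIVITY)
    primaries = []
    for entry in payload["primaries"]:
        lum = float(entry["mean_luminance"])
        if "lum_range" in entry and entry["lum_range"] is not None:
            lum_range = (float(entry["lum_range"][0]), float(entry["lum_range"][1]))
        else:
            lum_range = (0.0, 2.0 * lum)
            logger.warning(
                "config %s: primary %r has no luminance range; defaulting to [0, %g]",
                path,
                entry["name"],
                lum_range[1],
            )
        try:
            primaries.append(
                Primary(
                    name=entry["name"],
                    emission=Spectrum(grid, np.array(entry["emission"])),
                    mean_luminance=lum,
                    lum_range=lum_range,
                )
            )
        except ValueError as exc:
            raise ValueError(f"config {path}: invalid primary {entry['name']!r}: {exc}") from exc
    return Device(tuple(primaries), vlambda)


# ---------------------------------------------------------------------------
# Standard-observer bundle (one CSV per table, spectral CSV dialect)
# ---------------------------------------------------------------------------

_BUNDLE_FILES = {
    "cone_fundamentals.csv": ("L", "M", "S"),
    "rod_fundamental.csv": ("rod",),
    "melanopsin_fundamental.csv": ("mel",),
    "vlambda.csv": ("V",),
    "macular_density.csv": ("macular",),
    "lens_density.csv": ("TL1", "TL2"),
    "cmfs_1964.csv": ("xbar", "ybar", "zbar"),
}


def write_observer_bundle(
    directory: str | Path,
    observer: Observer,
    template: DensityTemplate,
    vlambda: Spectrum,
    cmfs: tuple[Spectrum, Spectrum, Spectrum],
) -> None:
    """Write a standard-observer bundle (one CSV per table)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    f = observer.fundamentals
    tables: dict[str, list[tuple[str, Spectrum]]] = {
        "cone_fundamentals.csv": [(n, f[n]) for n in ("L", "M", "S")],
        "rod_fundamental.csv": [("rod", f["rod"])],
        "melanopsin_fundamental.csv": [("mel", f["mel"])],
        "vlambda.csv": [("V", vlambda)],
        "macular_density.csv": [("macular", template.macular)],
        "lens_density.csv": [("TL1", template.lens_tl1), ("TL2", template.lens_tl2)],
        "cmfs_1964.csv": [("xbar", cmfs[0]), ("ybar", cmfs[1]), ("zbar", cmfs[2])],
    }
    for fname, spectra in tables.items():
        write_spectra(directory / fname, spectra)


def load_observer_bundle(
    directory: str | Path, grid: WavelengthGrid = CANONICAL_GRID
) -> tuple[Observer, DensityTemplate, Spectrum, tuple[Spectrum, Spectrum, Spectrum]]:
    """Load a standard-observer bundle written by :func:`write_observer_bundle`.

    Returns ``(observer, density_template, vlambda, cmfs)`` with every table
    resampled onto the canonical grid.
    """
    directory = Path(directory)
    columns: dict[str, Spectrum] = {}
    for fname, expected in _BUNDLE_FILES.items():
        fpath = directory / fname
        if not fpath.exists():
            raise FileNotFoundError(
                f"observer bundle at {directory} is missing {fname}; regenerate it "
                "with scripts/build_observer_bundle.py or use the synthetic observer"
            )
        table = pd.read_csv(fpath)
        wl = table.iloc[:, 0].to_numpy(dtype=float)
        src_grid = _grid_from_wavelengths(wl)
        for name in expected:
            if name not in table.columns:
                raise ValueError(f"{fpath}: expected a column named {name!r}")
            unit = UNIT_OPTICAL_DENSITY if fname in (
                "macular_density.csv", "lens_density.csv"
            ) else UNIT_SENSITIVITY
            values = table[name].to_numpy(dtype=float)
            if src_grid is not None:
                spectrum = Spectrum(src_grid, values, unit)
            else:
                spectrum = Spectrum(
                    grid, np.interp(grid.wavelengths, wl, values, left=0.0, right=0.0), unit
                )
            columns[name] = resample(spectrum, grid)
    observer = Observer({p: columns[p] for p in PHOTORECEPTORS})
    template = DensityTemplate(
        macular=columns["macular"], lens_tl1=columns["TL1"], lens_tl2=columns["TL2"]
    )
    cmfs = (columns["xbar"], columns["ybar"], columns["zbar"])
    return observer, template, columns["V"], cmfs
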