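"""Reading and writing spectral tables.

Two plain-CSV dialects are supported:

``long``
    one row per (spectrum, wavenumber):
    ``spectrum_id,donor_id,group,fluid,wavenumber,intensity``
``wide``
    one row per spectrum: the four metadata columns followed by one
    column per grid point, headed by the wavenumber value.

Floats are written with Python's shortest round-tripping repr, so a
write/read cycle reproduces intensities bit-exactly.  A JSON manifest is
written alongside each table recording the grid and basic counts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import META_COLUMNS, Cohort, SpectralGrid
from .errors import (
    DuplicateSpectrumError,
    ExtrapolationError,
    GridMismatchError,
    SpectralFormatError,
)

LONG_COLUMNS = list(META_COLUMNS) + ["wavenumber", "intensity"]


def _manifest_path(path: Path) -> Path:
    return path.with_name(path.name + ".manifest.json")


def write_manifest(cohort: Cohort, path, extra: dict | None = None) -> None:
    path = Path(path)
    manifest = {
        "grid": {
            "start_wavenumber": cohort.grid.start,
            "end_wavenumber": cohort.grid.end,
            "n_points": cohort.grid.n_points,
        },
        "n_spectra": cohort.n_spectra,
        "n_donors": len(cohort.donors()),
        "groups": {g: int((cohort.meta["group"] == g).sum()) for g in sorted(cohort.meta["group"].unique())} if cohort.n_spectra else {},
    }
    if extra:
        manifest.update(extra)
    _manifest_path(path).write_text(json.dumps(manifest, sort_keys=True, indent=2) + "\n")


def write_spectrum_table(cohort: Cohort, path, dialect: str = "long", manifest: bool = True) -> None:
    """Write a cohort to CSV in the requested dialect."""
    path = Path(path)
    wn = cohort.grid.wavenumbers
    if dialect == "long":
        n, p = cohort.intensities.shape
        frame = pd.DataFrame(
            {
                "spectrum_id": np.repeat(cohort.meta["spectrum_id"].to_numpy(), p),
                "donor_id": np.repeat(cohort.meta["donor_id"].to_numpy(), p),
                "group": np.repeat(cohort.meta["group"].to_numpy(), p),
                "fluid": np.repeat(cohort.meta["fluid"].to_numpy(), p),
                "wavenumber": np.tile(wn, n),
                "intensity": cohort.intensities.ravel(),
            }
        ) if n else pd.DataFrame(columns=LONG_COLUMNS)
        frame.to_csv(path, index=False)
    elif dialect == "wide":
        frame = cohort.meta.copy()
        value_cols = pd.DataFrame(cohort.intensities, columns=[repr(float(v)) for v in wn])
        frame = pd.concat([frame.reset_index(drop=True), value_cols], axis=1)
        frame.to_csv(path, index=False)
    else:
        raise SpectralFormatError(f"unknown dialect {dialect!r}")
    if manifest:
        write_manifest(cohort, path)


def read_spectrum_table(path, dialect: str = "long") -> Cohort:
    """Read a CSV spectral table back into a :class:`Cohort`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "long":
        return _read_long(path)
    if dialect == "wide":
        return _read_wide(path)
    raise SpectralFormatError(f"unknown dialect {dialect!r}")


def _read_long(path: Path) -> Cohort:
    frame = pd.read_csv(
        path, dtype={"spectrum_id": str, "donor_id": str}, float_precision="round_trip"
    )
    missing = [c for c in LONG_COLUMNS if c not in frame.columns]
    if missing:
        raise SpectralFormatError(f"{path}: missing columns {missing}")
    if frame.empty:
        return Cohort.empty()
    if frame.duplicated(subset=["spectrum_id", "wavenumber"]).any():
        raise DuplicateSpectrumError(f"{path}: duplicate (spectrum_id, wavenumber) rows")
    frame = frame.sort_values(["spectrum_id", "wavenumber"], kind="stable")
    grouped = frame.groupby("spectrum_id", sort=True)
    grid = None
    meta_rows, rows = [], []
    for sid, block in grouped:
        axis = block["wavenumber"].to_numpy(dtype=float)
        g = SpectralGrid.from_wavenumbers(axis)
        if grid is None:
            grid = g
        elif g != grid:
            raise GridMismatchError(f"{path}: spectrum {sid!r} is on a different grid")
        first = block.iloc[0]
        meta_rows.append((sid, first["donor_id"], first["group"], first["fluid"]))
        rows.append(block["intensity"].to_numpy(dtype=float))
    meta = pd.DataFrame(meta_rows, columns=list(META_COLUMNS))
    return Cohort(grid, meta, np.vstack(rows))


def _read_wide(path: Path) -> Cohort:
    frame = pd.read_csv(
        path, dtype={"spectrum_id": str, "donor_id": str}, float_precision="round_trip"
    )
    missing = [c for c in META_COLUMNS if c not in frame.columns]
    if missing:
        raise SpectralFormatError(f"{path}: missing columns {missing}")
    value_cols = [c for c in frame.columns if c not in META_COLUMNS]
    if not value_cols:
        raise SpectralFormatError(f"{path}: no wavenumber columns")
    try:
        axis = np.array([float(c) for c in value_cols])
    except ValueError as exc:
        raise SpectralFormatError(f"{path}: non-numeric wavenumber column header") from exc
    grid = SpectralGrid.from_wavenumbers(axis)
    meta = frame[list(META_COLUMNS)].copy()
    if meta["spectrum_id"].duplicated().any():
        raise DuplicateSpectrumError(f"{path}: duplicate spectrum_id rows")
    mat = frame[value_cols].to_numpy(dtype=float) if len(frame) else np.empty((0, grid.n_points))
    return Cohort(grid, meta, mat)


def resample_to_grid(intensities: np.ndarray, native_wavenumbers: np.ndarray, grid: SpectralGrid) -> np.ndarray:
    """Linearly interpolate a spectrum from its native axis onto ``grid``.

    The native axis must be strictly increasing and span the target grid;
    values at shared knots are preserved exactly.
    """
    y = np.asarray(intensities, dtype=float)
    x = np.asarray(native_wavenumbers, dtype=float)
    if x.ndim != 1 or x.size != y.size:
        raise SpectralFormatError("native axis and intensities must be 1-D and equal length")
    if np.any(np.diff(x) <= 0):
        raise SpectralFormatError("native axis must be strictly increasing")
    if grid.start < x[0] - 1e-12 or grid.end > x[-1] + 1e-12:
        raise ExtrapolationError(
            f"target grid [{grid.start}, {grid.end}] outside native span [{x[0]}, {x[-1]}]"
        )
    return np.interp(grid.wavenumbers, x, y)
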