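"""Hyperspectral map scans: band-intensity heat maps, hotspot
localization and multi-band co-localization.

A map scan is a rectangular lattice of stage positions (step width in
um) with one spectrum per position.  A heat map integrates the
baseline-subtracted signal over a window around a marker band (e.g. the
protein 1123, phospholipid 1270 and nucleic-acid 1341 cm^-1 bands); a
deposited vesicle shows up as a localized hotspot, and co-localization
of several bands at one spot indicates the substances co-exist in one
vesicle.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter

from .core import SpectralGrid
from .errors import DegenerateSpectrumError, SpectralFormatError
from .preprocess import als_baseline


@dataclass
class MapScan:
    """Grid of spectra: ``data[iy, ix]`` is the spectrum at (x[ix], y[iy])."""

    x: np.ndarray
    y: np.ndarray
    step_width: float
    grid: SpectralGrid
    data: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        if self.step_width <= 0:
            raise ValueError("step_width must be positive")
        expected = (self.y.size, self.x.size, self.grid.n_points)
        if self.data.shape != expected:
            raise SpectralFormatError(
                f"map data shape {self.data.shape} != lattice {expected}"
            )


@dataclass
class IntensityMap:
    """Band-intensity heat map aligned with the scan lattice."""

    values: np.ndarray
    band_center: float
    band_halfwidth: float
    x: np.ndarray
    y: np.ndarray
    step_width: float


def band_intensity(
    intensities: np.ndarray,
    grid: SpectralGrid,
    center: float,
    halfwidth: float,
    subtract_baseline: bool = True,
) -> float:
    """Trapezoidal integral of the (baseline-subtracted) signal over
    [center - halfwidth, center + halfwidth].

    Window edges falling between grid points are included by linear
    interpolation.  Baseline subtraction uses the standard ALS defaults;
    pass ``subtract_baseline=False`` for spectra already corrected.
    """
    lo, hi = center - halfwidth, center + halfwidth
    if lo < grid.start or hi > grid.end:
        raise ValueError(
            f"band window [{lo}, {hi}] outside grid [{grid.start}, {grid.end}]"
        )
    y = np.asarray(intensities, dtype=float)
    if subtract_baseline:
        y = y - als_baseline(y)
    wn = grid.wavenumbers
    inside = (wn > lo) & (wn < hi)
    xs = np.concatenate([[lo], wn[inside], [hi]])
    ys = np.concatenate([[np.interp(lo, wn, y)], y[inside], [np.interp(hi, wn, y)]])
    return float(np.trapezoid(ys, xs))


def build_intensity_map(
    scan: MapScan, center: float, halfwidth: float, subtract_baseline: bool = True
) -> IntensityMap:
    """Per-position band intensity over the whole lattice."""
    ny, nx, _ = scan.data.shape
    values = np.empty((ny, nx))
    for iy in range(ny):
        for ix in range(nx):
            values[iy, ix] = band_intensity(
                scan.data[iy, ix], scan.grid, center, halfwidth, subtract_baseline
            )
    return IntensityMap(
        values=values,
        band_center=center,
        band_halfwidth=halfwidth,
        x=scan.x,
        y=scan.y,
        step_width=scan.step_width,
    )


def locate_hotspot(imap: IntensityMap) -> tuple[float, float]:
    """Stage coordinates of the map maximum after 3x3 mean smoothing.

    Smoothing suppresses single-pixel noise spikes; among positions tied
    on the smoothed map the highest raw intensity wins (so an isolated
    bright pixel is still located exactly), then the lowest (row,
    column).  A constant map has no hotspot.
    """
    values = imap.values
    if np.ptp(values) == 0:
        raise DegenerateSpectrumError("constant intensity map has no hotspot")
    smoothed = uniform_filter(values, size=3, mode="nearest")
    ties = np.argwhere(smoothed == smoothed.max())
    raw = values[ties[:, 0], ties[:, 1]]
    best = ties[raw == raw.max()]
    iy, ix = min(map(tuple, best))
    return float(imap.x[ix]), float(imap.y[iy])


def colocalization(maps: list[IntensityMap]) -> pd.DataFrame:
    """Pairwise Pearson correlation between flattened band maps."""
    if len(maps) < 2:
        raise ValueError("need at least 2 maps")
    shapes = {m.values.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError("maps must share one lattice shape")
    rows = []
    for a, b in combinations(range(len(maps)), 2):
        va, vb = maps[a].values.ravel(), maps[b].values.ravel()
        if np.ptp(va) == 0 or np.ptp(vb) == 0:
            raise DegenerateSpectrumError("correlation undefined for a constant map")
        rows.append(
            {
                "band_a": maps[a].band_center,
                "band_b": maps[b].band_center,
                "pearson_r": float(np.corrcoef(va, vb)[0, 1]),
            }
        )
    return pd.DataFrame(rows, columns=["band_a", "band_b", "pearson_r"])


# -- plain-text round trip ------------------------------------------------

def write_map_scan(scan: MapScan, path) -> None:
    """Long CSV: x, y, wavenumber, intensity (one row per sample point)."""
    wn = scan.grid.wavenumbers
    ny, nx, p = scan.data.shape
    frame = pd.DataFrame(
        {
            "x": np.repeat(np.tile(scan.x, ny), p),
            "y": np.repeat(scan.y, nx * p),
            "wavenumber": np.tile(wn, ny * nx),
            "intensity": scan.data.ravel(),
        }
    )
    frame.to_csv(Path(path), index=False)


def read_map_scan(path) -> MapScan:
    frame = pd.read_csv(Path(path), float_precision="round_trip")
    missing = [c for c in ("x", "y", "wavenumber", "intensity") if c not in frame.columns]
    if missing:
        raise SpectralFormatError(f"{path}: missing columns {missing}")
    xs = np.array(sorted(frame["x"].unique()))
    ys = np.array(sorted(frame["y"].unique()))
    wn = np.array(sorted(frame["wavenumber"].unique()))
    grid = SpectralGrid.from_wavenumbers(wn)
    if len(frame) != xs.size * ys.size * wn.size:
        raise SpectralFormatError(f"{path}: positions do not form a complete lattice")
    step = float(xs[1] - xs[0]) if xs.size > 1 else float(ys[1] - ys[0])
    frame = frame.sort_values(["y", "x", "wavenumber"], kind="stable")
    data = frame["intensity"].to_numpy().reshape(ys.size, xs.size, wn.size)
    return MapScan(x=xs, y=ys, step_width=step, grid=grid, data=data)


def write_intensity_map(imap: IntensityMap, path) -> None:
    """Heat map as a CSV matrix (rows = y, columns = x)."""
    pd.DataFrame(imap.values, index=imap.y, columns=imap.x).to_csv(Path(path))


def render_intensity_map(imap: IntensityMap, path) -> None:
    """Save the heat map as an image (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    extent = (imap.x[0], imap.x[-1], imap.y[0], imap.y[-1])
    im = ax.imshow(imap.values, origin="lower", extent=extent, cmap="inferno")
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    ax.set_title(f"{imap.band_center:g} cm$^{{-1}}$ band")
    fig.colorbar(im, ax=ax, label="integrated intensity")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
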