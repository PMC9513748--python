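"""Core containers: the shared wavenumber grid, single spectra and cohorts.

A *fingerprint* is one vesicle's SERS intensity vector sampled on a shared
uniform wavenumber grid.  The default grid covers the biological
information-rich window 553-1581 cm^-1 with 1023 points (spacing about
1.006 cm^-1).  A :class:`Cohort` is the unit the analysis operates on: a
stack of fingerprints with donor / group / biofluid metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConsistencyError, DuplicateSpectrumError, GridMismatchError

GROUPS = ("GC", "control")
FLUIDS = ("tissue", "blood", "saliva")

#: metadata columns every cohort carries, in canonical order
META_COLUMNS = ("spectrum_id", "donor_id", "group", "fluid")


@dataclass(frozen=True)
class SpectralGrid:
    """Uniform, endpoint-inclusive wavenumber axis in cm^-1."""

    start: float = 553.0
    end: float = 1581.0
    n_points: int = 1023

    def __post_init__(self) -> None:
        if not (self.start < self.end):
            raise GridMismatchError(f"grid start {self.start} must be < end {self.end}")
        if self.n_points < 2:
            raise GridMismatchError("grid needs at least 2 points")

    @property
    def spacing(self) -> float:
        return (self.end - self.start) / (self.n_points - 1)

    @property
    def wavenumbers(self) -> np.ndarray:
        return np.linspace(self.start, self.end, self.n_points)

    @classmethod
    def from_wavenumbers(cls, wavenumbers: np.ndarray, rtol: float = 1e-9) -> "SpectralGrid":
        """Infer a grid from an observed axis, rejecting non-uniform spacing."""
        wn = np.asarray(wavenumbers, dtype=float)
        if wn.ndim != 1 or wn.size < 2:
            raise GridMismatchError("need a 1-D axis with >= 2 wavenumbers")
        diffs = np.diff(wn)
        if np.any(diffs <= 0):
            raise GridMismatchError("wavenumber axis must be strictly increasing")
        spacing = (wn[-1] - wn[0]) / (wn.size - 1)
        if np.max(np.abs(diffs - spacing)) > rtol * spacing:
            raise GridMismatchError("wavenumber axis is not uniform")
        return cls(float(wn[0]), float(wn[-1]), int(wn.size))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralGrid):
            return NotImplemented
        return (
            self.n_points == other.n_points
            and abs(self.start - other.start) <= 1e-9
            and abs(self.end - other.end) <= 1e-9
        )

    def __hash__(self) -> int:
        return hash((round(self.start, 6), round(self.end, 6), self.n_points))


DEFAULT_GRID = SpectralGrid()


@dataclass
class Spectrum:
    """One vesicle's fingerprint plus its identity metadata."""

    spectrum_id: str
    donor_id: str
    group: str
    fluid: str
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError(f"spectrum {self.spectrum_id}: non-finite intensities")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.fluid not in FLUIDS:
            raise ValueError(f"unknown fluid {self.fluid!r}; expected one of {FLUIDS}")


@dataclass
class Cohort:
    """A stack of fingerprints on one grid with per-spectrum metadata.

    ``meta`` is a DataFrame with columns ``spectrum_id, donor_id, group,
    fluid`` (one row per spectrum) and ``intensities`` the matching
    ``(n_spectra, grid.n_points)`` matrix, row-aligned with ``meta``.
    """

    grid: SpectralGrid
    meta: pd.DataFrame
    intensities: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.meta = self.meta.reset_index(drop=True)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim == 1 and self.intensities.size == 0:
            self.intensities = self.intensities.reshape(0, self.grid.n_points)
        self.validate()

    # -- construction -------------------------------------------------
    @classmethod
    def from_spectra(cls, spectra: list[Spectrum], grid: SpectralGrid | None = None) -> "Cohort":
        if grid is None:
            if not spectra:
                grid = DEFAULT_GRID
            else:
                n = spectra[0].intensities.size
                grid = SpectralGrid(DEFAULT_GRID.start, DEFAULT_GRID.end, n)
        meta = pd.DataFrame(
            [(s.spectrum_id, s.donor_id, s.group, s.fluid) for s in spectra],
            columns=list(META_COLUMNS),
        )
        if spectra:
            mat = np.vstack([s.intensities for s in spectra])
        else:
            mat = np.empty((0, grid.n_points))
        return cls(grid, meta, mat)

    @classmethod
    def empty(cls, grid: SpectralGrid | None = None) -> "Cohort":
        grid = grid or DEFAULT_GRID
        meta = pd.DataFrame(columns=list(META_COLUMNS))
        return cls(grid, meta, np.empty((0, grid.n_points)))

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ConsistencyError(f"cohort metadata missing columns {missing}")
        n = len(self.meta)
        if self.intensities.shape != (n, self.grid.n_points):
            raise GridMismatchError(
                f"intensity matrix {self.intensities.shape} does not match "
                f"{n} spectra x {self.grid.n_points} grid points"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("cohort contains non-finite intensities")
        ids = self.meta["spectrum_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise DuplicateSpectrumError(f"duplicate spectrum_id {dup!r}")
        groups_per_donor = self.meta.groupby("donor_id", sort=False)["group"].nunique()
        if (groups_per_donor > 1).any():
            bad = groups_per_donor[groups_per_donor > 1].index[0]
            raise ConsistencyError(f"donor {bad!r} mapped to more than one group")

    # -- convenience ---------------------------------------------------
    @property
    def n_spectra(self) -> int:
        return len(self.meta)

    @property
    def spectrum_ids(self) -> list[str]:
        return self.meta["spectrum_id"].tolist()

    def donors(self, group: str | None = None) -> list[str]:
        meta = self.meta if group is None else self.meta[self.meta["group"] == group]
        return sorted(meta["donor_id"].unique().tolist())

    def subset(self, mask: np.ndarray) -> "Cohort":
        mask = np.asarray(mask, dtype=bool)
        return Cohort(self.grid, self.meta[mask], self.intensities[mask])

    def select_fluid(self, fluid: str) -> "Cohort":
        return self.subset((self.meta["fluid"] == fluid).to_numpy())

    def select_group(self, group: str) -> "Cohort":
        return self.subset((self.meta["group"] == group).to_numpy())

    def select_donors(self, donor_ids) -> "Cohort":
        keep = set(donor_ids)
        return self.subset(self.meta["donor_id"].isin(keep).to_numpy())

    def drop_donors(self, donor_ids) -> "Cohort":
        drop = set(donor_ids)
        return self.subset(~self.meta["donor_id"].isin(drop).to_numpy())

    def matrix_for(self, spectrum_ids) -> np.ndarray:
        """Rows of the intensity matrix for the given ids, in the given order."""
        index = pd.Index(self.meta["spectrum_id"])
        locs = index.get_indexer(list(spectrum_ids))
        if (locs < 0).any():
            missing = [s for s, l in zip(spectrum_ids, locs) if l < 0]
            raise ConsistencyError(f"spectrum ids not in cohort: {missing[:5]}")
        return self.intensities[locs]

    def sorted_by_id(self) -> "Cohort":
        order = np.argsort(self.meta["spectrum_id"].to_numpy(), kind="stable")
        return Cohort(self.grid, self.meta.iloc[order], self.intensities[order])

    def iter_spectra(self):
        for i, row in enumerate(self.meta.itertuples(index=False)):
            yield Spectrum(row.spectrum_id, row.donor_id, row.group, row.fluid, self.intensities[i])
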