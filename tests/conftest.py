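"""Shared fixtures: synthetic cohorts at the sizes the test suite uses.

Cohort generation and preprocessing are the slow steps, so preprocessed
cohorts are built once per session and shared.  Three sizes are used:
the full default study design (15+15 donors, 50-70 spectra per sample)
for the relabeling-recovery checks, a 20-28 spectra/sample design for
the classifier and tracking checks, and a 12-16 spectra/sample design
for the donor-level leave-pair-out runs (which train one SVM per held
out pair).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sersev.core import Cohort, SpectralGrid
from sersev.preprocess import preprocess_cohort
from sersev.synthetic import SimConfig, generate_cohort

FLUIDS = ("tissue", "blood", "saliva")


def preprocess_all(cohorts: dict) -> dict:
    return {fluid: preprocess_cohort(c)[0] for fluid, c in cohorts.items()}


@pytest.fixture(scope="session")
def default_low_noise():
    """Full default study design in the well-separated (low-noise) regime."""
    cohorts, truth = generate_cohort(SimConfig.low_noise())
    return preprocess_all(cohorts), truth


@pytest.fixture(scope="session")
def small_default():
    """Default noise, 20-28 spectra per sample."""
    cohorts, truth = generate_cohort(SimConfig(spectra_per_sample=(20, 28)))
    return preprocess_all(cohorts), truth


@pytest.fixture(scope="session")
def lposo_tissue():
    """Tissue cohort sized for per-pair retraining, preprocessed."""
    cohorts, _ = generate_cohort(SimConfig(spectra_per_sample=(12, 16)))
    return preprocess_cohort(cohorts["tissue"])[0]


def random_cohort(rng: np.random.Generator, n_spectra: int = 4, n_points: int = 16) -> Cohort:
    """Small random cohort on a compact grid (for I/O and contract tests)."""
    grid = SpectralGrid(600.0, 600.0 + n_points - 1, n_points)
    meta = pd.DataFrame(
        {
            "spectrum_id": [f"s{i:03d}" for i in range(n_spectra)],
            "donor_id": [f"d{i % 3}" for i in range(n_spectra)],
            "group": [("GC" if (i % 3) < 2 else "control") for i in range(n_spectra)],
            "fluid": ["blood"] * n_spectra,
        }
    )
    return Cohort(grid, meta, rng.normal(size=(n_spectra, n_points)))


def permute_donor_groups(cohort: Cohort, seed: int) -> Cohort:
    """Reassign donors to groups uniformly at random (null cohort)."""
    rng = np.random.default_rng(seed)
    donors = sorted(cohort.meta["donor_id"].unique())
    perm = rng.permutation(donors)
    half = len(perm) // 2
    mapping = {d: ("GC" if i < half else "control") for i, d in enumerate(perm)}
    meta = cohort.meta.copy()
    meta["group"] = meta["donor_id"].map(mapping)
    return Cohort(cohort.grid, meta, cohort.intensities)
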