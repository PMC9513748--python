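"""Label-noise correction for patient spectra.

Cancer patients also carry normal vesicles, so a naive labeling scheme
(every spectrum from a patient sample = "GC") mislabels the normal
fraction and dilutes the class signal.  The correction cross-compares
each patient fingerprint against the control group: a patient spectrum
whose nearest control neighbor lies within tau shares common spectral
features with the controls and is treated as a normal vesicle, while the
remainder form the patient-unique population (PP).  Only PP spectra keep
the "GC" training label; everything else is relabeled "control".

Comparison is performed per biofluid (PP in tissue / blood / saliva are
the PT / PB / PS populations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Cohort
from .errors import ConsistencyError
from .fingerprint import derive_threshold, nearest_neighbor_distances

logger = logging.getLogger(__name__)


@dataclass
class RelabelResult:
    """Partition of patient spectra into patient-unique vs common."""

    pp_ids: frozenset[str]
    common_ids: frozenset[str]
    threshold_used: float

    def __post_init__(self) -> None:
        if self.pp_ids & self.common_ids:
            raise ConsistencyError("pp_ids and common_ids overlap")

    @property
    def patient_ids(self) -> frozenset[str]:
        return self.pp_ids | self.common_ids

    @property
    def training_labels(self) -> dict[str, str]:
        labels = {sid: "GC" for sid in self.pp_ids}
        labels.update({sid: "control" for sid in self.common_ids})
        return labels


def extract_pp(
    patient_matrix: np.ndarray,
    patient_ids: list[str],
    control_matrix: np.ndarray,
    tau: float,
    metric: str = "euclidean",
) -> RelabelResult:
    """Split patient spectra at nearest-control-neighbor distance tau."""
    patient_matrix = np.atleast_2d(np.asarray(patient_matrix, dtype=float))
    if len(patient_ids) != patient_matrix.shape[0]:
        raise ConsistencyError("patient_ids length does not match matrix rows")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    nn = nearest_neighbor_distances(patient_matrix, control_matrix, metric)
    common = frozenset(sid for sid, d in zip(patient_ids, nn) if d <= tau)
    pp = frozenset(patient_ids) - common
    return RelabelResult(pp_ids=pp, common_ids=common, threshold_used=float(tau))


def relabel_fluid(
    cohort: Cohort, percentile: float = 95.0, metric: str = "euclidean"
) -> RelabelResult:
    """Derive tau from the cohort's controls and extract PP in one step.

    ``cohort`` must hold preprocessed spectra of a single biofluid.
    """
    patients = cohort.select_group("GC")
    controls = cohort.select_group("control")
    if controls.n_spectra < 2:
        raise ValueError("need at least 2 control spectra to derive tau")
    tau = derive_threshold(controls.intensities, percentile, metric)
    return extract_pp(
        patients.intensities, patients.spectrum_ids, controls.intensities, tau, metric
    )


def apply_relabel(cohort: Cohort, result: RelabelResult) -> pd.DataFrame:
    """Build the training table: cohort metadata plus the corrected label.

    Every patient spectrum must be covered by ``result``; control-donor
    spectra always keep the "control" label.  Rows are sorted by
    spectrum_id for determinism.
    """
    patient_ids = set(cohort.select_group("GC").spectrum_ids)
    covered = result.patient_ids
    missing = patient_ids - covered
    if missing:
        raise ConsistencyError(
            f"relabel result does not cover {len(missing)} patient spectra"
        )
    labels = result.training_labels
    table = cohort.meta.copy()
    table["label"] = [
        labels.get(sid, "control") if grp == "GC" else "control"
        for sid, grp in zip(table["spectrum_id"], table["group"])
    ]
    return table.sort_values("spectrum_id", kind="stable").reset_index(drop=True)


def labeled_matrix(cohort: Cohort, table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Intensity matrix and binary labels aligned with a training table."""
    ids = table["spectrum_id"].tolist()
    X = cohort.matrix_for(ids)
    y = (table["label"] == "GC").to_numpy(dtype=int)
    return X, y, ids


def compare_relabel_cv(
    cohort: Cohort,
    percentile: float = 95.0,
    rounds: int = 20,
    seed: int = 0,
    params=None,
):
    """Paired cross-validation with and without label correction.

    Both arms use identical 80/20 splits (stratified on the raw donor
    group so the split does not depend on the label scheme) and are
    scored against the same reference — the corrected labels, which are
    the best available spectrum-level truth (a normal vesicle from a
    patient genuinely is not a cancer marker).  The arms differ only in
    the labels trained on: raw group labels vs corrected labels.
    Returns ``(report_raw, report_relabel, relabel_result)``.
    """
    from .classify import cross_validate  # local import avoids a cycle

    result = relabel_fluid(cohort, percentile)
    table = apply_relabel(cohort, result)
    X, y_relabel, ids = labeled_matrix(cohort, table)
    meta = cohort.meta.set_index("spectrum_id").loc[ids]
    strata = (meta["group"] == "GC").to_numpy(dtype=int)
    y_raw = strata.copy()
    if not result.pp_ids:
        # no patient-unique spectra at this tau: the relabeled task is
        # undefined (one class), so the arm degenerates to raw labels
        logger.warning("relabeling left no PP spectra; comparing raw vs raw")
        y_relabel = y_raw
    report_raw = cross_validate(
        X, y_raw, rounds=rounds, seed=seed, params=params, strata=strata,
        y_eval=y_relabel,
    )
    report_relabel = cross_validate(
        X, y_relabel, rounds=rounds, seed=seed, params=params, strata=strata
    )
    return report_raw, report_relabel, result


def pp_fraction_by_donor(cohort: Cohort, result: RelabelResult) -> pd.Series:
    """Fraction of each patient donor's spectra that are patient-unique."""
    patients = cohort.select_group("GC")
    is_pp = patients.meta["spectrum_id"].isin(result.pp_ids)
    return is_pp.groupby(patients.meta["donor_id"]).mean()
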