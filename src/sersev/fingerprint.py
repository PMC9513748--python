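"""Fingerprint similarity, hierarchical clustering and the common/unique
decision threshold.

The working hypothesis of single-vesicle SERS subtyping is that spectral
differences *across* vesicle types outweigh the internal variation
*within* a type, so Euclidean distance between preprocessed fingerprints
separates types.  Hierarchical clustering groups fingerprints into vesicle
types; a control-calibrated percentile of leave-self-out nearest-neighbor
distances provides the single data-driven threshold tau reused by the
relabeling and cross-fluid tracking steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import cdist, squareform

METRICS = ("euclidean", "one_minus_pearson")
LINKAGES = ("average", "complete", "single")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise-distance matrix with its spectrum id order."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match id count")


@dataclass
class SubtypeAssignment:
    """Partition of spectra into vesicle types."""

    labels: dict[str, int]

    @property
    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for sid, t in self.labels.items():
            out.setdefault(t, []).append(sid)
        return out

    @property
    def n_types(self) -> int:
        return len(set(self.labels.values()))


def _metric_values(X: np.ndarray, Y: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        return cdist(X, Y, metric="euclidean")
    if metric == "one_minus_pearson":
        return cdist(X, Y, metric="correlation")
    raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")


def pairwise_distances(
    X: np.ndarray, metric: str = "euclidean", ids: list[str] | None = None
) -> DistanceMatrix:
    """All-pairs distances between fingerprint rows."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if ids is None:
        ids = [str(i) for i in range(X.shape[0])]
    values = _metric_values(X, X, metric)
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(list(ids), values)


def nearest_neighbor_distances(
    query: np.ndarray, reference: np.ndarray, metric: str = "euclidean"
) -> np.ndarray:
    """Distance from each query fingerprint to its closest reference."""
    query = np.atleast_2d(np.asarray(query, dtype=float))
    reference = np.atleast_2d(np.asarray(reference, dtype=float))
    if reference.shape[0] == 0:
        raise ValueError("reference set is empty")
    return _metric_values(query, reference, metric).min(axis=1)


def nearest_neighbor_indices(
    query: np.ndarray, reference: np.ndarray, metric: str = "euclidean"
) -> np.ndarray:
    """Index of each query's nearest reference; ties break to the lowest index."""
    query = np.atleast_2d(np.asarray(query, dtype=float))
    reference = np.atleast_2d(np.asarray(reference, dtype=float))
    if reference.shape[0] == 0:
        raise ValueError("reference set is empty")
    return _metric_values(query, reference, metric).argmin(axis=1)


def hcluster(distmat: DistanceMatrix, method: str = "average") -> np.ndarray:
    """Agglomerative clustering; returns the (n-1, 4) merge table.

    Each row of the result is ``(left, right, height, size)`` in scipy's
    linkage convention.
    """
    if method not in LINKAGES:
        raise ValueError(f"unknown linkage {method!r}; expected one of {LINKAGES}")
    n = len(distmat.ids)
    if n < 2:
        raise ValueError("need at least 2 spectra to cluster")
    condensed = squareform(distmat.values, checks=False)
    return scipy_linkage(condensed, method=method)


def assign_subtypes(
    merges: np.ndarray, cut_height: float, ids: list[str]
) -> SubtypeAssignment:
    """Cut a dendrogram: types are the components left after removing all
    merges above ``cut_height``."""
    if cut_height < 0:
        raise ValueError("cut_height must be >= 0")
    flat = fcluster(merges, t=cut_height, criterion="distance")
    return SubtypeAssignment({sid: int(t) for sid, t in zip(ids, flat)})


def leave_self_out_nn_distances(X: np.ndarray, metric: str = "euclidean") -> np.ndarray:
    """Within-set nearest-neighbor distances, excluding each point itself."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("need at least 2 spectra")
    d = _metric_values(X, X, metric)
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def derive_threshold(
    control_matrix: np.ndarray, percentile: float = 95.0, metric: str = "euclidean"
) -> float:
    """Common/unique decision threshold tau.

    tau is the given percentile of leave-self-out nearest-neighbor
    distances within the control set: a patient fingerprint closer than
    tau to some control fingerprint is as close as control fingerprints
    typically are to each other, i.e. spectroscopically 'common'.
    """
    if not (0.0 < percentile <= 100.0):
        raise ValueError("percentile must lie in (0, 100]")
    nn = leave_self_out_nn_distances(control_matrix, metric)
    return float(np.percentile(nn, percentile))
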