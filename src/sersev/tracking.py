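"""Tracking patient-unique vesicle types across biofluids.

Patient-unique (PP) fingerprints from tissue (PT), blood (PB) and saliva
(PS) are clustered into vesicle types per fluid; a tissue type is
considered *tracked* when it has a mutually-nearest centroid match within
tau in both blood and saliva.  Tracked types get a per-fluid membership,
per-fluid centroids, an overall mean spectrum, and a source-distribution
table (how many member vesicles came from each fluid).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .fingerprint import DistanceMatrix, SubtypeAssignment, assign_subtypes, hcluster, pairwise_distances

logger = logging.getLogger(__name__)

FLUID_ORDER = ("tissue", "blood", "saliva")


def cluster_pp_types(
    X: np.ndarray, ids: list[str], cut_height: float, method: str = "single"
) -> SubtypeAssignment:
    """Cluster one fluid's PP fingerprints into vesicle types.

    Single linkage is the default here because the cut height is tau, a
    nearest-neighbor-distance percentile: cutting a single-linkage tree
    at tau yields exactly the connected components of the 'within tau of
    a neighbor' graph, the same semantics tau has in relabeling.
    Average-linkage merge heights are mean pairwise distances, which are
    systematically larger than nearest-neighbor distances, so an
    average-linkage cut at tau over-fragments the types.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        return SubtypeAssignment({})
    if X.shape[0] == 1:
        return SubtypeAssignment({ids[0]: 1})
    merges = hcluster(pairwise_distances(X, ids=ids), method=method)
    return assign_subtypes(merges, cut_height, ids)


@dataclass
class TypeSet:
    """Per-fluid vesicle types: members and centroid fingerprints."""

    fluid: str
    members: dict[int, list[str]]
    centroids: dict[int, np.ndarray]

    @classmethod
    def from_assignment(
        cls, fluid: str, assignment: SubtypeAssignment, X: np.ndarray, ids: list[str]
    ) -> "TypeSet":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        row = {sid: i for i, sid in enumerate(ids)}
        members = assignment.members
        centroids = {
            t: X[[row[sid] for sid in sids]].mean(axis=0) for t, sids in members.items()
        }
        return cls(fluid=fluid, members=members, centroids=centroids)

    @property
    def type_ids(self) -> list[int]:
        return sorted(self.members)

    def centroid_matrix(self) -> tuple[list[int], np.ndarray]:
        tids = self.type_ids
        return tids, np.vstack([self.centroids[t] for t in tids])


@dataclass
class MatchedType:
    """One vesicle type observed in all three fluids."""

    type_id: int
    members_by_fluid: dict[str, list[str]]
    centroid_by_fluid: dict[str, np.ndarray]
    mean_spectrum: np.ndarray

    @property
    def counts_by_fluid(self) -> dict[str, int]:
        return {f: len(m) for f, m in self.members_by_fluid.items()}


@dataclass
class TrackingResult:
    matched_types: list[MatchedType]

    @property
    def n_types(self) -> int:
        return len(self.matched_types)


def _mutual_nearest(a: np.ndarray, b: np.ndarray, tau: float) -> dict[int, int]:
    """Row index of ``a`` -> row index of ``b`` for mutually nearest pairs
    within tau; empty inputs give an empty map."""
    if a.shape[0] == 0 or b.shape[0] == 0:
        return {}
    d = cdist(a, b)
    a_to_b = d.argmin(axis=1)
    b_to_a = d.argmin(axis=0)
    return {
        i: j
        for i, j in enumerate(a_to_b)
        if b_to_a[j] == i and d[i, j] <= tau
    }


def match_types_across_fluids(
    types_tissue: TypeSet,
    types_blood: TypeSet,
    types_saliva: TypeSet,
    tau_track: float,
    pp_matrices: dict[str, tuple[np.ndarray, list[str]]] | None = None,
) -> TrackingResult:
    """Tissue types with mutually-nearest centroid matches (within tau)
    in both blood and saliva.

    ``pp_matrices`` maps fluid -> (matrix, ids) and is needed to compute
    each matched type's overall mean spectrum from its member spectra;
    without it the mean is taken over the three centroids weighted by
    member counts (identical result).
    """
    for ts in (types_tissue, types_blood, types_saliva):
        if not ts.members:
            logger.warning("no PP types in %s; tracking result is empty", ts.fluid)
            return TrackingResult(matched_types=[])
    t_ids, t_cent = types_tissue.centroid_matrix()
    b_ids, b_cent = types_blood.centroid_matrix()
    s_ids, s_cent = types_saliva.centroid_matrix()
    to_blood = _mutual_nearest(t_cent, b_cent, tau_track)
    to_saliva = _mutual_nearest(t_cent, s_cent, tau_track)
    matched = []
    for i, tissue_tid in enumerate(t_ids):
        if i not in to_blood or i not in to_saliva:
            continue
        blood_tid = b_ids[to_blood[i]]
        saliva_tid = s_ids[to_saliva[i]]
        members = {
            "tissue": sorted(types_tissue.members[tissue_tid]),
            "blood": sorted(types_blood.members[blood_tid]),
            "saliva": sorted(types_saliva.members[saliva_tid]),
        }
        centroids = {
            "tissue": types_tissue.centroids[tissue_tid],
            "blood": types_blood.centroids[blood_tid],
            "saliva": types_saliva.centroids[saliva_tid],
        }
        counts = {f: len(m) for f, m in members.items()}
        if pp_matrices is not None:
            rows = []
            for fluid in FLUID_ORDER:
                X, ids = pp_matrices[fluid]
                row = {sid: k for k, sid in enumerate(ids)}
                rows.append(np.atleast_2d(X)[[row[sid] for sid in members[fluid]]])
            mean_spectrum = np.vstack(rows).mean(axis=0)
        else:
            total = sum(counts.values())
            mean_spectrum = (
                sum(counts[f] * centroids[f] for f in FLUID_ORDER) / total
            )
        matched.append(
            MatchedType(
                type_id=tissue_tid,
                members_by_fluid=members,
                centroid_by_fluid=centroids,
                mean_spectrum=mean_spectrum,
            )
        )
    return TrackingResult(matched_types=matched)


def source_distribution(result: TrackingResult) -> pd.DataFrame:
    """Tidy per-type member counts by fluid of origin."""
    rows = [
        {"type_id": mt.type_id, **{f: mt.counts_by_fluid[f] for f in FLUID_ORDER}}
        for mt in result.matched_types
    ]
    return pd.DataFrame(rows, columns=["type_id", *FLUID_ORDER])
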