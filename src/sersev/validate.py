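"""Donor-level "leave-a-pair-of-samples-out" (LPOSO) validation.

Ordinary spectrum-level cross-validation lets spectra from a donor appear
on both sides of the split, which flatters the accuracy.  LPOSO instead
holds out one cancer donor and one control donor at a time: relabeling
threshold, kernel bandwidth and the SVM itself are derived from the
remaining donors only, and the held-out pair is scored at the sample
level.  Pairs are drawn without replacement until every donor has been
left out once (one round); rounds are repeated (default 10) and the ROC /
AUC of the pooled sample scores is reported per round, then averaged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .classify import ClassifierParams, train_classifier
from .core import Cohort
from .fingerprint import derive_threshold
from .relabel import extract_pp

AGGREGATORS = ("mean", "fraction_positive")

logger = logging.getLogger(__name__)


@dataclass
class LposoSchedule:
    """Per-round donor pairings: rounds[r] is a list of (GC, control) pairs."""

    rounds: list[list[tuple[str, str]]]
    seed: int


def lposo_schedule(cohort: Cohort, rounds: int = 10, seed: int = 0) -> LposoSchedule:
    """Uniform random pairing without replacement, per round.

    Requires equal, non-empty donor groups (the study design is n per
    group on both sides); every donor appears in exactly one pair per
    round.
    """
    gc = cohort.donors("GC")
    ctrl = cohort.donors("control")
    if len(gc) < 2 or len(ctrl) < 2:
        raise ValueError("need at least 2 donors per group")
    if len(gc) != len(ctrl):
        raise ValueError(
            f"pairing requires equal group sizes, got {len(gc)} GC vs {len(ctrl)} control"
        )
    out = []
    for r in range(rounds):
        rng = np.random.default_rng([int(seed), 104729, r])
        order_gc = rng.permutation(len(gc))
        order_ctrl = rng.permutation(len(ctrl))
        out.append([(gc[i], ctrl[j]) for i, j in zip(order_gc, order_ctrl)])
    return LposoSchedule(rounds=out, seed=seed)


def sample_score(spectrum_margins: np.ndarray, aggregator: str = "mean") -> float:
    """Aggregate one donor sample's spectrum margins into a donor score."""
    margins = np.asarray(spectrum_margins, dtype=float)
    if margins.size == 0:
        raise ValueError("sample has no spectra")
    if aggregator == "mean":
        return float(margins.mean())
    if aggregator == "fraction_positive":
        return float((margins > 0).mean())
    raise ValueError(f"unknown aggregator {aggregator!r}; expected one of {AGGREGATORS}")


@dataclass
class RocResult:
    """One ROC sweep: false/true positive rates, thresholds and AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_and_auc(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """ROC over all score thresholds; AUC is the rank statistic
    (probability a random positive outscores a random negative, ties 1/2).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("need both positive and negative labels")
    fpr, tpr, thr = roc_curve(labels, scores)
    auc = float(roc_auc_score(labels, scores))
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


@dataclass
class Evaluation:
    """One held-out pair: scores plus an audit trail of what was trained on."""

    round_index: int
    gc_donor: str
    control_donor: str
    gc_score: float
    control_score: float
    training_donors: list[str]
    tau: float
    gamma: float
    n_pp: int
    n_common: int


@dataclass
class LposoReport:
    """All evaluations, per-round ROC/AUC and the averaged AUC."""

    evaluations: list[Evaluation]
    round_rocs: list[RocResult]
    round_aucs: list[float]
    aggregator: str
    seed: int

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.round_aucs))

    def to_dict(self) -> dict:
        return {
            "mean_auc": self.mean_auc,
            "round_aucs": [float(a) for a in self.round_aucs],
            "rounds": len(self.round_aucs),
            "aggregator": self.aggregator,
            "seed": self.seed,
            "n_evaluations": len(self.evaluations),
        }


def run_lposo(
    cohort: Cohort,
    rounds: int = 10,
    seed: int = 0,
    relabel: bool = True,
    percentile: float = 95.0,
    aggregator: str = "mean",
    params: ClassifierParams | None = None,
) -> LposoReport:
    """Full leave-a-pair-of-samples-out validation of one biofluid cohort.

    ``cohort`` must hold preprocessed spectra of a single fluid.  For each
    held-out pair the relabeling threshold tau is recomputed from the
    *training* controls only, the patient training spectra are relabeled
    (if ``relabel``), the SVM trained and the two held-out samples scored
    by aggregating their spectrum margins.
    """
    schedule = lposo_schedule(cohort, rounds=rounds, seed=seed)
    evaluations: list[Evaluation] = []
    round_rocs: list[RocResult] = []
    round_aucs: list[float] = []
    for r, pairs in enumerate(schedule.rounds):
        scores, labels = [], []
        for gc_donor, ctrl_donor in pairs:
            train = cohort.drop_donors([gc_donor, ctrl_donor])
            patients = train.select_group("GC")
            controls = train.select_group("control")
            tau = derive_threshold(controls.intensities, percentile)
            if relabel:
                result = extract_pp(
                    patients.intensities, patients.spectrum_ids, controls.intensities, tau
                )
                pp = result.pp_ids
                if not pp:
                    # relabeling found no patient-unique spectra in this
                    # fold (tau too permissive on a small control set);
                    # fall back to the raw labels so the fold still
                    # yields a classifier
                    logger.warning(
                        "round %d pair (%s, %s): relabeling left no PP "
                        "spectra; training this fold on raw labels",
                        r, gc_donor, ctrl_donor,
                    )
                    pp = frozenset(patients.spectrum_ids)
            else:
                pp = frozenset(patients.spectrum_ids)
            y_train = np.concatenate(
                [
                    np.array([1 if sid in pp else 0 for sid in patients.spectrum_ids]),
                    np.zeros(controls.n_spectra, dtype=int),
                ]
            )
            X_train = np.vstack([patients.intensities, controls.intensities])
            model = train_classifier(X_train, y_train, params)
            held_gc = cohort.select_donors([gc_donor])
            held_ctrl = cohort.select_donors([ctrl_donor])
            s_gc = sample_score(model.decision_score(held_gc.intensities), aggregator)
            s_ctrl = sample_score(model.decision_score(held_ctrl.intensities), aggregator)
            scores += [s_gc, s_ctrl]
            labels += [1, 0]
            evaluations.append(
                Evaluation(
                    round_index=r,
                    gc_donor=gc_donor,
                    control_donor=ctrl_donor,
                    gc_score=s_gc,
                    control_score=s_ctrl,
                    training_donors=sorted(train.donors()),
                    tau=float(tau),
                    gamma=float(model.gamma),
                    n_pp=len(pp),
                    n_common=patients.n_spectra - len(pp),
                )
            )
        roc = roc_and_auc(np.array(scores), np.array(labels))
        round_rocs.append(roc)
        round_aucs.append(roc.auc)
    return LposoReport(
        evaluations=evaluations,
        round_rocs=round_rocs,
        round_aucs=round_aucs,
        aggregator=aggregator,
        seed=seed,
    )
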