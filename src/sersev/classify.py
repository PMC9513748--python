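"""Supervised classification of fingerprints and the cross-validation
protocol.

The classifier is an RBF-kernel support vector machine.  Hyperparameters
are fixed, not searched: regularization weight 1.0 on a size-invariant
penalty scale, kernel bandwidth from the median pairwise-distance
heuristic on the training fingerprints, and inverse-class-frequency
sample weights to compensate imbalance (the patient-unique class shrinks
after relabeling).

Validation follows an 80/20 stratified split repeated for 20 independent
rounds; prediction accuracy is the fraction of correct calls on the
held-out 20%.  Linear discriminant analysis with a shrinkage-regularized
within-class scatter (necessary because p = 1023 far exceeds n) provides
the low-dimensional projection used for visualization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.svm import SVC

#: nominal sample count the SVM penalty is normalized to, so that the
#: effective regularization does not depend on dataset size (duplicating
#: every training row leaves the decision function unchanged)
EFFECTIVE_N = 200.0


def accuracy(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Prediction accuracy: correct predictions over total predictions."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have equal length")
    if predicted.size == 0:
        raise ValueError("empty label vectors")
    return float(np.mean(predicted == truth))


def median_heuristic_gamma(X: np.ndarray, max_rows: int = 800) -> float:
    """RBF bandwidth gamma = 1 / (2 * median pairwise distance squared).

    The median is taken over unique fingerprints (so repeated rows do not
    shift the bandwidth); for large training sets an evenly strided,
    deterministic subsample is used.
    """
    X = np.unique(np.asarray(X, dtype=float), axis=0)
    if X.shape[0] > max_rows:
        stride = int(np.ceil(X.shape[0] / max_rows))
        X = X[::stride]
    med = np.median(pdist(X))
    if med <= 0:
        return 1.0 / X.shape[1]
    return float(1.0 / (2.0 * med**2))


@dataclass
class ClassifierParams:
    """Fixed SVM settings (no hyperparameter search)."""

    C: float = 1.0
    kernel: str = "rbf"
    tol: float = 1e-6


@dataclass
class SVMFingerprint:
    """Trained margin classifier: positive decision score means 'GC'."""

    model: SVC
    gamma: float
    classes: tuple[str, str] = ("control", "GC")

    def decision_score(self, X: np.ndarray) -> np.ndarray:
        return self.model.decision_function(np.atleast_2d(X))

    def predict_label(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_score(X)
        return np.where(scores > 0, self.classes[1], self.classes[0])

    def predict_binary(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_score(X) > 0).astype(int)


def train_classifier(
    X: np.ndarray, y: np.ndarray, params: ClassifierParams | None = None
) -> SVMFingerprint:
    """Fit the RBF SVM.  ``y`` is binary with 1 = GC.

    Sample weights are inverse class frequencies normalized so each class
    contributes a total weight of EFFECTIVE_N / 2 regardless of size.
    """
    params = params or ClassifierParams()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("training data must contain both classes")
    gamma = median_heuristic_gamma(X)
    weight_per_class = {c: EFFECTIVE_N / (2.0 * n) for c, n in zip(classes, counts)}
    sample_weight = np.array([weight_per_class[c] for c in y])
    model = SVC(C=params.C, kernel=params.kernel, gamma=gamma, tol=params.tol)
    model.fit(X, y, sample_weight=sample_weight)
    return SVMFingerprint(model=model, gamma=gamma)


@dataclass
class LDAProjection:
    """Discriminant directions and per-spectrum scores (LD1 = column 0)."""

    directions: np.ndarray
    scores: np.ndarray
    class_labels: np.ndarray


def lda_project(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int | None = None,
    shrinkage: float = 0.1,
) -> LDAProjection:
    """Shrinkage-regularized LDA projection for visualization."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    max_comp = len(classes) - 1
    if n_components is None:
        n_components = max_comp
    if n_components > max_comp:
        raise ValueError(f"n_components must be <= {max_comp} for {len(classes)} classes")
    lda = LinearDiscriminantAnalysis(
        solver="eigen", shrinkage=float(shrinkage), n_components=n_components
    )
    scores = lda.fit(X, y).transform(X)
    return LDAProjection(
        directions=lda.scalings_[:, :n_components], scores=scores, class_labels=classes
    )


@dataclass
class CVReport:
    """Per-round held-out accuracies of repeated 80/20 validation."""

    round_accuracies: list[float]
    seed: int
    train_fraction: float

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.round_accuracies))

    @property
    def variance(self) -> float:
        # population variance, matching a per-round spread statistic
        return float(np.var(self.round_accuracies))

    def to_dict(self) -> dict:
        return {
            "round_accuracies": [float(a) for a in self.round_accuracies],
            "mean_accuracy": self.mean_accuracy,
            "variance": self.variance,
            "rounds": len(self.round_accuracies),
            "train_fraction": self.train_fraction,
            "seed": self.seed,
        }


def stratified_split(
    strata: np.ndarray, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random per-stratum 80/20 split; returns (train_idx, test_idx)."""
    strata = np.asarray(strata)
    train_parts, test_parts = [], []
    for value in np.unique(strata):
        idx = np.flatnonzero(strata == value)
        n_train = int(round(train_fraction * idx.size))
        if n_train == 0 or n_train == idx.size:
            raise ValueError(f"stratum {value!r} too small to split at {train_fraction}")
        perm = rng.permutation(idx)
        train_parts.append(perm[:n_train])
        test_parts.append(perm[n_train:])
    return np.sort(np.concatenate(train_parts)), np.sort(np.concatenate(test_parts))


def round_rng(master_seed: int, round_index: int) -> np.random.Generator:
    """Counter-based per-round RNG: child seed = (master, round_index)."""
    return np.random.default_rng([int(master_seed), int(round_index)])


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    train_fraction: float = 0.8,
    rounds: int = 20,
    seed: int = 0,
    params: ClassifierParams | None = None,
    strata: np.ndarray | None = None,
    y_eval: np.ndarray | None = None,
) -> CVReport:
    """Repeated stratified 80/20 cross-validation of the SVM.

    Each round draws an independent stratified split (stratified on ``y``
    unless explicit ``strata`` are given, e.g. raw donor groups when
    comparing label schemes on identical splits), trains on the 80% and
    scores accuracy on the disjoint 20%.  ``y_eval`` scores the held-out
    spectra against a different label reference than the one trained on
    (used when label schemes are compared against a common reference);
    by default the training labels are also the evaluation labels.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    y_eval = y if y_eval is None else np.asarray(y_eval, dtype=int)
    strata = y if strata is None else np.asarray(strata)
    for value in np.unique(strata):
        if (strata == value).sum() < 5:
            raise ValueError("every stratum needs >= 5 spectra to split 80/20")
    accs = []
    for r in range(rounds):
        train_idx, test_idx = stratified_split(strata, train_fraction, round_rng(seed, r))
        assert np.intersect1d(train_idx, test_idx).size == 0
        model = train_classifier(X[train_idx], y[train_idx], params)
        accs.append(accuracy(model.predict_binary(X[test_idx]), y_eval[test_idx]))
    return CVReport(round_accuracies=accs, seed=seed, train_fraction=train_fraction)
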