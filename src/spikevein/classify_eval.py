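"""Feature selection, one-vs-rest linear classification, and biometric
metrics.

The binary spike features are optionally filtered by a chi-square score
(keeping the top percentile of columns), classified with a linear
maximum-margin one-vs-rest model (hinge loss, penalty C), and scored with
the standard biometric verification metrics:

    Accuracy = N_T / N * 100
    FAR(thr) = FA / (FA + TA)   over impostor (between-class) comparisons
    FRR(thr) = FR / (FR + TR)   over genuine (within-class) comparisons

The equal error rate (EER) is the operating point where FAR = FRR,
obtained by sweeping a decision threshold over the pooled genuine and
impostor one-vs-rest decision scores and linearly interpolating between
the bracketing thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import LinearSVC

__all__ = [
    "FeatureTable",
    "MetricsReport",
    "chi2_scores",
    "select_features_chi2",
    "fit_predict_linear_ovr",
    "compute_metrics",
]


@dataclass
class FeatureTable:
    """Nonnegative sample-by-feature matrix with class labels."""

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.min() < 0:
            raise ValueError("chi-square scoring requires nonnegative features")
        if len(self.y) != self.X.shape[0]:
            raise ValueError("labels must align with rows of X")


@dataclass
class MetricsReport:
    """Verification metrics and the score sets they were computed from."""

    accuracy: float  # percent
    eer: float  # percent
    thresholds: np.ndarray
    far_curve: np.ndarray
    frr_curve: np.ndarray
    genuine_scores: np.ndarray = field(repr=False, default=None)
    impostor_scores: np.ndarray = field(repr=False, default=None)


def chi2_scores(table: FeatureTable) -> np.ndarray:
    """Chi-square statistic of each feature against the class labels.

    For feature j, score_j = sum_c (O_cj - E_cj)^2 / E_cj where O_cj is the
    feature's total over class-c samples and E_cj the class-share-weighted
    grand total. Features with zero grand total score 0.
    """
    classes, y_idx = np.unique(table.y, return_inverse=True)
    n_classes = len(classes)
    n, _ = table.X.shape
    observed = np.zeros((n_classes, table.X.shape[1]))
    np.add.at(observed, y_idx, table.X)
    class_share = np.bincount(y_idx, minlength=n_classes) / n
    totals = table.X.sum(axis=0)
    expected = class_share[:, None] * totals[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (observed - expected) ** 2 / expected, 0.0)
    return terms.sum(axis=0)


def select_features_chi2(table: FeatureTable, percentile: float) -> np.ndarray:
    """Indices of the top ``percentile`` percent of columns by chi-square
    score, ties broken stably by lower column index; returned sorted."""
    if not (0 < percentile <= 100):
        raise ValueError("percentile must lie in (0, 100]")
    scores = chi2_scores(table)
    n = scores.size
    n_keep = n if percentile == 100 else max(1, int(np.ceil(percentile / 100.0 * n)))
    order = np.lexsort((np.arange(n), -scores))  # score desc, then index asc
    return np.sort(order[:n_keep])


def fit_predict_linear_ovr(
    train: FeatureTable, test_X: np.ndarray, C: float = 2.4
) -> tuple[np.ndarray, np.ndarray]:
    """One-vs-rest linear SVM: fit on the training table, score the test set.

    Returns predicted labels (argmax of the decision scores) and the full
    samples-by-classes decision-score matrix for EER computation.
    """
    classes = np.unique(train.y)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    clf = LinearSVC(C=C)
    clf.fit(train.X, train.y)
    scores = clf.decision_function(np.asarray(test_X, dtype=np.float64))
    scores = np.atleast_2d(scores)
    labels = clf.classes_[np.argmax(scores, axis=1)]
    return labels, scores


def compute_metrics(scores: np.ndarray, y_true: np.ndarray) -> MetricsReport:
    """Accuracy, FAR/FRR curves and interpolated EER from a score matrix.

    Each row's true-class score is a genuine comparison; every other entry
    is an impostor comparison. A comparison is accepted when its score is
    at or above the decision threshold; the threshold is swept over the
    pooled score range.
    """
    scores = np.asarray(scores, dtype=np.float64)
    y_true = np.asarray(y_true)
    if scores.ndim != 2 or scores.shape[0] != len(y_true):
        raise ValueError("scores must be samples x classes aligned with y_true")
    classes = np.unique(y_true)
    if scores.shape[1] != len(classes):
        raise ValueError("score columns must correspond to the unique labels")
    col_of = {c: i for i, c in enumerate(classes)}
    true_cols = np.array([col_of[c] for c in y_true])

    predicted = np.argmax(scores, axis=1)
    accuracy = float(np.mean(predicted == true_cols) * 100.0)

    genuine = scores[np.arange(len(y_true)), true_cols]
    mask = np.ones_like(scores, dtype=bool)
    mask[np.arange(len(y_true)), true_cols] = False
    impostor = scores[mask]
    if genuine.size == 0 or impostor.size == 0:
        raise ValueError("empty genuine or impostor score set")

    pooled = np.unique(np.concatenate([genuine, impostor]))
    # extend one step past both ends so FAR spans [0,1] and FRR spans [0,1]
    lo = pooled[0] - 1.0
    hi = pooled[-1] + 1.0
    thresholds = np.concatenate(([lo], pooled, [hi]))
    far = np.array([(impostor >= t).mean() for t in thresholds])
    frr = np.array([(genuine < t).mean() for t in thresholds])

    eer = _interpolated_eer(thresholds, far, frr) * 100.0
    return MetricsReport(
        accuracy=accuracy,
        eer=eer,
        thresholds=thresholds,
        far_curve=far,
        frr_curve=frr,
        genuine_scores=genuine,
        impostor_scores=impostor,
    )


def _interpolated_eer(thresholds: np.ndarray, far: np.ndarray, frr: np.ndarray) -> float:
    """Crossing point of FAR (non-increasing) and FRR (non-decreasing)."""
    diff = far - frr
    idx = np.flatnonzero(diff <= 0)
    if idx.size == 0:  # curves never cross inside the sweep (degenerate)
        return float(min(far[-1], frr[-1]))
    i = idx[0]
    if i == 0 or diff[i] == 0:
        return float((far[i] + frr[i]) / 2.0)
    # linear interpolation between the bracketing thresholds i-1 and i
    d0, d1 = diff[i - 1], diff[i]
    w = d0 / (d0 - d1)
    far_x = far[i - 1] + w * (far[i] - far[i - 1])
    frr_x = frr[i - 1] + w * (frr[i] - frr[i - 1])
    return float((far_x + frr_x) / 2.0)
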