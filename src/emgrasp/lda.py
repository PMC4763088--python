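"""Linear discriminant analysis for EMG motion classification.

The classifier is the Gaussian equal-covariance model: per-class mean
feature vectors, one pooled within-class covariance (optionally shrunk
toward a trace-scaled identity), and linear discriminant scores

    d_k(x) = x' S^{-1} m_k - 0.5 m_k' S^{-1} m_k + log pi_k .

Priors default to equal across classes — class balance is controlled by the
collection protocol, not estimated from it.  Ties in the argmax break toward
the earlier class in ``model.classes``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_SHRINKAGE = 1e-6


@dataclass
class LdaModel:
    classes: tuple[str, ...]
    means: np.ndarray          # (k, d)
    covariance: np.ndarray     # (d, d), pooled within-class, shrinkage applied
    priors: np.ndarray         # (k,)
    shrinkage: float
    weights: np.ndarray = field(init=False)   # (k, d)
    biases: np.ndarray = field(init=False)    # (k,)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        self.priors = np.asarray(self.priors, dtype=float)
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("priors must sum to 1")
        try:
            wt = np.linalg.solve(self.covariance, self.means.T)  # (d, k)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "pooled covariance is singular; increase the shrinkage parameter"
            ) from exc
        self.weights = wt.T
        self.biases = -0.5 * np.einsum("kd,kd->k", self.means, self.weights) + np.log(
            self.priors
        )

    @property
    def n_features(self) -> int:
        return self.means.shape[1]


def train_lda(features, labels, shrinkage: float = DEFAULT_SHRINKAGE,
              priors=None, classes=None) -> LdaModel:
    """Fit an LDA model from labelled feature vectors.

    Parameters
    ----------
    features : (n, d) array
    labels : length-n sequence of class identifiers
    shrinkage
        Ridge added to the pooled covariance as
        ``shrinkage * trace(S)/d * I``.  The small default keeps
        near-singular 120-dimensional pooled covariances invertible.
    priors
        ``None`` (equal), ``"empirical"``, or an explicit length-k vector.
    classes
        Optional explicit class ordering; defaults to order of first
        appearance in ``labels``.

    Raises
    ------
    ValueError
        If fewer than two classes are present, or any class has fewer than
        two samples (the class is named).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features must be (n, d) with one label per row")
    if classes is None:
        _, first = np.unique(y, return_index=True)
        classes = tuple(y[np.sort(first)])
    else:
        classes = tuple(classes)
        present = set(np.unique(y))
        missing = [c for c in classes if c not in present]
        if missing:
            raise ValueError(f"class(es) {missing} have no training samples")
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to train LDA")
    k, d = len(classes), X.shape[1]
    means = np.empty((k, d))
    counts = np.empty(k, dtype=int)
    scatter = np.zeros((d, d))
    for i, c in enumerate(classes):
        Xi = X[y == c]
        counts[i] = Xi.shape[0]
        if counts[i] < 2:
            raise ValueError(f"class {c!r} has {counts[i]} sample(s); at least 2 required")
        means[i] = Xi.mean(axis=0)
        Z = Xi - means[i]
        scatter += Z.T @ Z
    cov = scatter / (counts.sum() - k)
    if shrinkage:
        cov = cov + shrinkage * (np.trace(cov) / d) * np.eye(d)
    if priors is None:
        pri = np.full(k, 1.0 / k)
    elif isinstance(priors, str) and priors == "empirical":
        pri = counts / counts.sum()
    else:
        pri = np.asarray(priors, dtype=float)
        if pri.shape != (k,):
            raise ValueError("priors vector length must match number of classes")
        pri = pri / pri.sum()
    return LdaModel(classes=classes, means=means, covariance=cov, priors=pri,
                    shrinkage=float(shrinkage))


def decision_scores(model: LdaModel, features) -> np.ndarray:
    """Linear discriminant scores, shape ``(n, k)``."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} != model dimension {model.n_features}"
        )
    return X @ model.weights.T + model.biases


def predict(model: LdaModel, x) -> str:
    """Class of a single feature vector (argmax score; ties -> earlier class)."""
    scores = decision_scores(model, np.asarray(x, dtype=float)[None, :])
    return model.classes[int(np.argmax(scores[0]))]


def predict_batch(model: LdaModel, features) -> np.ndarray:
    scores = decision_scores(model, features)
    idx = np.argmax(scores, axis=1)
    return np.asarray(model.classes, dtype=object)[idx]


def classification_error(predicted, truth) -> float:
    """Percentage of incorrect classifications, in [0, 100]."""
    p = np.asarray(predicted)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError("predicted and truth must have equal length")
    if p.size == 0:
        raise ValueError("cannot compute classification error of empty sequences")
    return 100.0 * float(np.mean(p != t))


def assign_folds(repetitions) -> np.ndarray:
    """Two-fold assignment: repetitions alternate into folds in collection order."""
    reps = np.asarray(repetitions, dtype=int)
    return (reps - reps.min()) % 2


def two_fold_cv(features, labels, folds, shrinkage: float = DEFAULT_SHRINKAGE,
                priors=None, classes=None, return_folds: bool = False):
    """Mean two-fold cross-validated classification error (percent).

    Folds are split by repetition (never by frame).  Each class must appear
    in both folds.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    f = np.asarray(folds)
    fold_ids = np.unique(f)
    if fold_ids.size != 2:
        raise ValueError(f"expected exactly 2 folds, got {fold_ids.size}")
    for c in np.unique(y):
        present = {bool(np.any((y == c) & (f == fid))) for fid in fold_ids}
        if present != {True}:
            raise ValueError(f"class {c!r} is not present in both folds")
    errs = []
    for train_id, test_id in (fold_ids, fold_ids[::-1]):
        tr = f == train_id
        te = f == test_id
        model = train_lda(X[tr], y[tr], shrinkage=shrinkage, priors=priors, classes=classes)
        errs.append(classification_error(predict_batch(model, X[te]), y[te]))
    mean = float(np.mean(errs))
    if return_folds:
        return mean, tuple(errs)
    return mean
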