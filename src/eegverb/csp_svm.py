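"""One-vs-one Common Spatial Patterns + RBF-SVM baseline decoder.

For each of the C(6,2) = 15 unordered verb pairs, CSP filters are learned
from the pair's class-mean normalised covariance matrices and a pairwise
RBF-kernel support-vector classifier is trained on the log-variance
features; a test trial is classified by majority vote over the 15 pairwise
decisions.

CSP for a pair (a, b) solves the generalised eigenproblem

    C_a w = lambda (C_a + C_b) w

where C_k is the class-mean of per-trial normalised covariances
C = D D^T / trace(D D^T).  Eigenvalues lie in [0, 1]; eigenvectors with
extreme eigenvalues maximise the variance ratio between the classes.  The
feature vector of a filtered trial Z = W D is

    f_j = log( var(Z_j) / sum_{i=1}^{2m} var(Z_i) )

with m filters retained from each end of the spectrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import linalg
from sklearn.svm import SVC

from .containers import TrialSet

#: Default CSP filters per side; 2m = 6 features per pair for 8 channels.
DEFAULT_M = 3
DEFAULT_SVM_C = 1.0
SHRINKAGE = 1e-6
VAR_FLOOR = np.finfo(float).tiny


class DegenerateTrialError(ValueError):
    """Trial has zero total power; its covariance is undefined."""


class DecompositionError(np.linalg.LinAlgError):
    """Composite covariance singular even after shrinkage."""


def normalized_covariance(data: np.ndarray) -> np.ndarray:
    """Trace-normalised spatial covariance ``D D^T / trace(D D^T)``."""
    d = np.asarray(data, dtype=float)
    if d.ndim != 2 or d.shape[1] < 2:
        raise ValueError("trial must be channels x time with >= 2 time points")
    c = d @ d.T
    tr = np.trace(c)
    if tr <= 0 or not np.isfinite(tr):
        raise DegenerateTrialError("trial has zero (or non-finite) total power")
    return c / tr


def class_mean_covariance(ts: TrialSet) -> np.ndarray:
    """Arithmetic mean of per-trial normalised covariances, with shrinkage.

    A small shrinkage toward the scaled identity guarantees the composite
    matrix in the generalised eigensolve stays positive definite.
    """
    n = ts.n_channels
    c = np.zeros((n, n))
    for i in range(len(ts)):
        c += normalized_covariance(ts.data[i])
    c /= len(ts)
    return (1.0 - SHRINKAGE) * c + SHRINKAGE * (np.trace(c) / n) * np.eye(n)


@dataclass
class SpatialFilterBank:
    """CSP filters for one class pair.

    ``filters`` is the 2m x channels matrix W (rows sorted by descending
    eigenvalue: the first m maximise class-a variance share, the last m
    maximise class-b's); ``eigenvalues`` are the associated generalised
    eigenvalues in [0, 1].
    """

    pair: tuple[int, int]
    filters: np.ndarray
    eigenvalues: np.ndarray


def fit_csp_pair(trials_a: TrialSet, trials_b: TrialSet,
                 m: int = DEFAULT_M) -> SpatialFilterBank:
    """Learn the pairwise CSP filter bank from two single-class trial sets."""
    if len(trials_a) == 0 or len(trials_b) == 0:
        raise ValueError("both classes must be non-empty")
    n = trials_a.n_channels
    if 2 * m > n:
        raise ValueError(f"2m = {2 * m} filters exceed {n} channels")
    ca = class_mean_covariance(trials_a)
    cb = class_mean_covariance(trials_b)
    composite = ca + cb
    try:
        evals, evecs = linalg.eigh(ca, composite)
    except linalg.LinAlgError as exc:  # pragma: no cover - shrinkage prevents this
        raise DecompositionError(str(exc)) from exc
    # eigh returns ascending order; keep m from each end, sorted descending
    order = np.argsort(evals)[::-1]
    keep = np.concatenate([order[:m], order[-m:]]) if 2 * m < n else order
    evals, evecs = evals[keep], evecs[:, keep]
    w = evecs.T
    # reproducible sign: largest-magnitude coefficient of each filter positive
    signs = np.sign(w[np.arange(w.shape[0]), np.argmax(np.abs(w), axis=1)])
    w = w * signs[:, None]
    la = int(trials_a.labels[0]) if len(trials_a) else 0
    lb = int(trials_b.labels[0]) if len(trials_b) else 1
    return SpatialFilterBank((la, lb), w, np.clip(evals, 0.0, 1.0))


def csp_features(data: np.ndarray, bank: SpatialFilterBank) -> np.ndarray:
    """Normalised log-variance features of one trial (or a trial stack).

    Accepts (channels, time) or (n_trials, channels, time); returns a
    length-2m vector or an (n_trials, 2m) matrix.
    """
    d = np.asarray(data, dtype=float)
    single = d.ndim == 2
    if single:
        d = d[None]
    z = np.einsum("fc,nct->nft", bank.filters, d)
    v = z.var(axis=2)
    if np.any(v <= 0):
        warnings.warn("zero-variance filtered component; flooring", stacklevel=2)
        v = np.maximum(v, VAR_FLOOR)
    f = np.log(v / v.sum(axis=1, keepdims=True))
    return f[0] if single else f


@dataclass
class OvoCspModel:
    """All pairwise filter banks and classifiers of the one-vs-one decoder."""

    n_classes: int
    m: int
    banks: dict[tuple[int, int], SpatialFilterBank]
    classifiers: dict[tuple[int, int], SVC]


def fit_ovo(train: TrialSet, m: int = DEFAULT_M,
            svm_c: float = DEFAULT_SVM_C,
            svm_g: float | None = None) -> OvoCspModel:
    """Train the one-vs-one CSP + RBF-SVM decoder.

    ``svm_g`` is the RBF width coefficient g in exp(-g ||x - x'||^2);
    the default 1 / (2m) scales with the feature dimensionality.
    """
    classes = np.unique(train.labels)
    if any(len(train.for_class(int(c))) < 2 for c in classes):
        raise ValueError("need >= 2 trials per class to train")
    gamma = svm_g if svm_g is not None else 1.0 / (2 * m)
    banks, clfs = {}, {}
    for a, b in combinations(sorted(int(c) for c in classes), 2):
        ta, tb = train.for_class(a), train.for_class(b)
        bank = fit_csp_pair(ta, tb, m)
        bank.pair = (a, b)
        x = np.vstack([csp_features(ta.data, bank), csp_features(tb.data, bank)])
        y = np.concatenate([np.full(len(ta), a), np.full(len(tb), b)])
        clf = SVC(C=svm_c, kernel="rbf", gamma=gamma)
        clf.fit(x, y)
        banks[(a, b)] = bank
        clfs[(a, b)] = clf
    return OvoCspModel(len(classes), m, banks, clfs)


def predict_ovo(model: OvoCspModel, ts: TrialSet) -> tuple[np.ndarray, np.ndarray]:
    """Majority-vote prediction over all pairwise classifiers.

    Returns ``(labels, votes)`` with ``votes`` of shape (n_trials,
    n_classes) summing to the number of pairs per row.  Ties are broken by
    the summed absolute decision-function margins of the tied classes'
    classifiers (deterministic, confidence-weighted).
    """
    n = len(ts)
    votes = np.zeros((n, model.n_classes))
    margin = np.zeros((n, model.n_classes))
    for (a, b), clf in model.classifiers.items():
        x = csp_features(ts.data, model.banks[(a, b)])
        dec = clf.decision_function(x)  # positive side = clf.classes_[1]
        hi, lo = int(clf.classes_[1]), int(clf.classes_[0])
        winner = np.where(dec > 0, hi, lo)
        votes[np.arange(n), winner] += 1
        margin[np.arange(n), winner] += np.abs(dec)
    # argmax over (votes, margin) lexicographically
    best = votes + margin / (1.0 + margin.max() * (votes.max() + 1))
    labels = best.argmax(axis=1)
    return labels, votes


class CspSvmDecoder:
    """Convenience train/predict wrapper used by the evaluation protocols."""

    def __init__(self, m: int = DEFAULT_M, svm_c: float = DEFAULT_SVM_C,
                 svm_g: float | None = None):
        self.m, self.svm_c, self.svm_g = m, svm_c, svm_g
        self.model: OvoCspModel | None = None

    def fit(self, train: TrialSet, seed: int = 0) -> "CspSvmDecoder":
        self.model = fit_ovo(train, self.m, self.svm_c, self.svm_g)
        return self

    def predict(self, ts: TrialSet) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("decoder not fitted")
        return predict_ovo(self.model, ts)[0]
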