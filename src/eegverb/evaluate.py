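"""Metrics and the three evaluation protocols of the verb-decoding study.

From a 6x6 confusion matrix C (rows = true verb, columns = predicted):

    accuracy    = sum_i C_ii / sum_ij C_ij
    precision_i = TP_i / (TP_i + FP_i)
    recall_i    = TP_i / (TP_i + FN_i)
    F1_i        = 2 precision_i recall_i / (precision_i + recall_i)

in a one-vs-rest reading per verb.  WER for this isolated six-word task is
defined as 1 - trial accuracy (not an edit distance).  All protocols are
subject-specific, within-dataset: models are trained and tested within each
participant's own trials and the reported dispersion is the across-subject
sample standard deviation.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import TrialSet
from .preprocess import split_trials

logger = logging.getLogger(__name__)


class LabelError(ValueError):
    """A label fell outside the class range."""


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray  # (k, k) ints; rows true, columns predicted

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(y_true, y_pred, n_classes: int = 6) -> ConfusionMatrix:
    """Count (true i, predicted j) pairs into a k x k matrix."""
    t = np.asarray(y_true, dtype=int)
    p = np.asarray(y_pred, dtype=int)
    if t.shape != p.shape:
        raise LabelError("label sequences must have equal length")
    if t.size and (t.min() < 0 or t.max() >= n_classes
                   or p.min() < 0 or p.max() >= n_classes):
        raise LabelError(f"labels must lie in [0, {n_classes})")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts)


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: np.ndarray  # per class, NaN where undefined (0/0)
    recall: np.ndarray
    f1: np.ndarray
    wer: float

    @property
    def macro_precision(self) -> float:
        return float(np.nanmean(self.precision))

    @property
    def macro_recall(self) -> float:
        return float(np.nanmean(self.recall))

    @property
    def macro_f1(self) -> float:
        return float(np.nanmean(self.f1))


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, per-class precision/recall/F1 and WER from counts.

    Per-class ratios with zero denominators (a class absent from both the
    truth and the predictions) are reported as NaN sentinels and excluded
    from the macro averages.
    """
    c = cm.counts.astype(float)
    tp = np.diag(c)
    fp = c.sum(axis=0) - tp
    fn = c.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), np.nan)
        recall = np.where(tp + fn > 0, tp / (tp + fn), np.nan)
        f1 = np.where(np.nan_to_num(precision) + np.nan_to_num(recall) > 0,
                      2 * precision * recall / (precision + recall), np.nan)
        f1 = np.where(np.isnan(precision) & np.isnan(recall), np.nan, f1)
        f1 = np.where((precision == 0) & (recall == 0), 0.0, f1)
    accuracy = float(tp.sum() / c.sum()) if c.sum() else np.nan
    return MetricsReport(accuracy, precision, recall, f1, 1.0 - accuracy)


def subject_level_summary(accuracies) -> tuple[float, float]:
    """Across-subject mean and sample standard deviation.

    With a single subject the dispersion is undefined and reported as NaN.
    """
    a = np.asarray(list(accuracies), dtype=float)
    mean = float(a.mean())
    sd = float(a.std(ddof=1)) if len(a) >= 2 else float("nan")
    return mean, sd


def _per_subject_accuracy(decoder_factory, train_ts: TrialSet,
                          test_ts: TrialSet, seed: int) -> list[float]:
    """Train and test within each subject; return per-subject accuracies."""
    accs = []
    for sid in np.unique(train_ts.subjects):
        dec = decoder_factory().fit(train_ts.for_subject(int(sid)), seed=seed)
        sub_test = test_ts.for_subject(int(sid))
        pred = dec.predict(sub_test)
        accs.append(float((pred == sub_test.labels).mean()))
    return accs


def evaluate_split(decoder_factory, train_ts: TrialSet, test_ts: TrialSet,
                   seed: int = 0, pooled: bool = False):
    """Accuracy of a decoder on one train/test split.

    ``pooled=True`` trains a single model on all subjects together (used
    for scaled synthetic checks); the default is the study's
    subject-specific protocol.
    """
    if pooled:
        dec = decoder_factory().fit(train_ts, seed=seed)
        pred = dec.predict(test_ts)
        return float((pred == test_ts.labels).mean())
    accs = _per_subject_accuracy(decoder_factory, train_ts, test_ts, seed)
    return subject_level_summary(accs)


def repetitions_curve(ts: TrialSet, decoder_factory, reps_grid,
                      seed: int = 0, test_proportion: float = 1.0 / 3.0,
                      pooled: bool = True) -> pd.DataFrame:
    """Accuracy as a function of training repetitions per verb per subject.

    A fixed stratified test partition is held out once; for each grid value
    r, r trials per (subject, class) are drawn (nested: larger r extends
    smaller r) from the remaining pool, a decoder is trained and scored.
    Grid points exceeding the available pool are skipped with a warning.
    The returned frame also carries the Spearman rank correlation between
    repetitions and accuracy as ``df.attrs["spearman_rho"]``.
    """
    pool, test = split_trials(ts, 1.0 - test_proportion, seed)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x2E9]))
    # one nested random order per stratum
    orders = {}
    for sid in np.unique(pool.subjects):
        for lab in np.unique(pool.labels):
            idx = np.flatnonzero((pool.subjects == sid) & (pool.labels == lab))
            orders[(int(sid), int(lab))] = rng.permutation(idx)
    max_reps = min(len(v) for v in orders.values())

    rows = []
    for r in sorted(set(int(r) for r in reps_grid)):
        if r < 1 or r > max_reps:
            warnings.warn(f"skipping reps={r}: only {max_reps} per stratum "
                          "available", stacklevel=2)
            continue
        take = np.sort(np.concatenate([v[:r] for v in orders.values()]))
        acc = evaluate_split(decoder_factory, pool[take], test,
                             seed=seed, pooled=pooled)
        if isinstance(acc, tuple):
            acc = acc[0]
        rows.append({"reps": r, "accuracy": acc})
    df = pd.DataFrame(rows)
    if len(df) >= 2 and df["accuracy"].nunique() > 1:
        df.attrs["spearman_rho"] = float(
            stats.spearmanr(df["reps"], df["accuracy"]).statistic)
    return df


def proportion_curve(ts: TrialSet, decoder_factory, proportion_grid,
                     seed: int = 0, pooled: bool = True) -> pd.DataFrame:
    """Accuracy and wall-time vs. training-data proportion.

    Wall-time is informational only (hardware-dependent).
    """
    rows = []
    for p in proportion_grid:
        train_ts, test_ts = split_trials(ts, float(p), seed)
        t0 = time.perf_counter()
        acc = evaluate_split(decoder_factory, train_ts, test_ts,
                             seed=seed, pooled=pooled)
        if isinstance(acc, tuple):
            acc = acc[0]
        rows.append({"proportion": float(p), "n_train": len(train_ts),
                     "accuracy": acc,
                     "train_time_s": time.perf_counter() - t0})
    return pd.DataFrame(rows)


def lr_curve(ts: TrialSet, lr_grid, seed: int = 0,
             train_proportion: float = 2.0 / 3.0,
             decoder_factory=None) -> pd.DataFrame:
    """WER (= 1 - accuracy) of the recurrent decoder across learning rates.

    All rates share the same split, initialisation seed and schedule; a
    diverged run is recorded as WER 1.0 with ``diverged=True`` rather than
    raising.
    """
    from .dual_lstm import LstmDecoder, TrainConfig, TrainingDivergedError

    train_ts, test_ts = split_trials(ts, train_proportion, seed)
    rows = []
    for lr in lr_grid:
        if lr <= 0:
            raise ValueError("learning rates must be positive")
        factory = decoder_factory or (
            lambda lr=lr: LstmDecoder(config=TrainConfig(learning_rate=float(lr))))
        try:
            dec = factory(lr) if decoder_factory else factory()
            dec.fit(train_ts, seed=seed)
            pred = dec.predict(test_ts)
            wer = 1.0 - float((pred == test_ts.labels).mean())
            diverged = False
        except TrainingDivergedError as exc:
            logger.warning("lr=%g diverged: %s", lr, exc)
            wer, diverged = 1.0, True
        rows.append({"lr": float(lr), "wer": wer, "diverged": diverged})
    return pd.DataFrame(rows)


def compare_methods(ts: TrialSet, decoder_factories: dict, seed: int = 0,
                    train_proportion: float = 2.0 / 3.0,
                    pooled: bool = True) -> pd.DataFrame:
    """Train every decoder on one shared split; report accuracy per method."""
    train_ts, test_ts = split_trials(ts, train_proportion, seed)
    rows = []
    for name, factory in decoder_factories.items():
        dec = factory().fit(train_ts, seed=seed) if pooled else None
        if pooled:
            pred = dec.predict(test_ts)
            acc, sd = float((pred == test_ts.labels).mean()), float("nan")
        else:
            acc, sd = evaluate_split(factory, train_ts, test_ts, seed=seed)
        rows.append({"method": name, "accuracy": acc, "sd": sd,
                     "n_test": len(test_ts)})
    return pd.DataFrame(rows)


def chance_interval(n_trials: int, n_classes: int = 6,
                    confidence: float = 0.99) -> tuple[float, float]:
    """Binomial confidence band around chance accuracy 1/k for n trials."""
    p = 1.0 / n_classes
    lo, hi = stats.binom.interval(confidence, n_trials, p)
    return lo / n_trials, hi / n_trials
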