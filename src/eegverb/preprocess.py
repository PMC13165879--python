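"""Front-end: band-pass filtering, channel selection, epoching, splitting.

The acquisition front end is a 4-45 Hz band-pass (covering theta, alpha and
beta while excluding drift and 50 Hz line interference), restriction to the
eight language-area electrodes, and extraction of the 4-s task window
following each stimulus onset (1000 samples at 250 Hz).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import signal as sps

from .containers import (
    DEFAULT_MONTAGE,
    ExperimentDesign,
    MontageError,
    RawRecording,
    SplitError,
    TrialSet,
)

logger = logging.getLogger(__name__)

DEFAULT_BAND = (4.0, 45.0)
FILTER_ORDER = 4  # Butterworth order; applied forward-backward (zero-phase)
DEFAULT_REJECT_UV = 100.0


def design_bandpass(low: float, high: float, sample_rate: float,
                    order: int = FILTER_ORDER) -> np.ndarray:
    """Second-order sections of the Butterworth band-pass front end."""
    nyq = sample_rate / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < "
            f"Nyquist ({nyq} Hz)")
    return sps.butter(order, (low, high), btype="bandpass",
                      fs=sample_rate, output="sos")


def bandpass_array(x: np.ndarray, sample_rate: float,
                   low: float = DEFAULT_BAND[0],
                   high: float = DEFAULT_BAND[1]) -> np.ndarray:
    """Zero-phase band-pass along the last axis."""
    sos = design_bandpass(low, high, sample_rate)
    return sps.sosfiltfilt(sos, x, axis=-1)


def bandpass(recording: RawRecording, low: float = DEFAULT_BAND[0],
             high: float = DEFAULT_BAND[1]) -> RawRecording:
    """Band-pass every channel, preserving shape and event timing.

    Forward-backward filtering has zero group delay, so stimulus-locked
    epoch boundaries remain valid on the filtered signal.
    """
    filtered = bandpass_array(recording.samples, recording.sample_rate, low, high)
    return RawRecording(filtered, recording.channel_names,
                        recording.sample_rate, recording.events,
                        recording.subject_id)


def select_channels(recording: RawRecording,
                    montage: tuple[str, ...] = DEFAULT_MONTAGE) -> RawRecording:
    """Subset and reorder channels to ``montage`` order.

    The default montage is the eight language-area electrodes: Broca
    (F5, FT7, FC5, FC3) then Wernicke (TP7, CP5, CP3, P5).
    """
    index = {name: i for i, name in enumerate(recording.channel_names)}
    missing = [name for name in montage if name not in index]
    if missing:
        raise MontageError(
            f"channel(s) {missing} not present in recording "
            f"(available: {list(recording.channel_names)})")
    rows = [index[name] for name in montage]
    return RawRecording(recording.samples[rows], tuple(montage),
                        recording.sample_rate, recording.events,
                        recording.subject_id)


def epoch(recording: RawRecording, design: ExperimentDesign) -> TrialSet:
    """Cut one task-window epoch per stimulus event.

    Windows are half-open ``[onset, onset + task samples)`` with 0-based
    onsets.  Trials whose window would run past the end of the recording
    are dropped and logged.
    """
    n = design.n_task_samples
    data, labels, blocks = [], [], []
    dropped = 0
    for ev in recording.events:
        if ev.kind != "stimulus":
            continue
        if ev.onset + n > recording.n_samples:
            dropped += 1
            logger.warning(
                "dropping stimulus at sample %d: window of %d samples "
                "exceeds recording length %d", ev.onset, n, recording.n_samples)
            continue
        data.append(recording.samples[:, ev.onset:ev.onset + n])
        labels.append(ev.label)
        blocks.append(ev.block)
    if dropped:
        warnings.warn(f"dropped {dropped} truncated trial(s)", stacklevel=2)
    shape = (len(data), len(recording.channel_names), n)
    arr = np.array(data) if data else np.empty(shape)
    return TrialSet(arr, labels, [recording.subject_id] * len(labels), blocks,
                    recording.channel_names, recording.sample_rate)


def reject_artifacts(ts: TrialSet,
                     threshold_uv: float = DEFAULT_REJECT_UV) -> TrialSet:
    """Drop trials whose absolute amplitude exceeds ``threshold_uv``.

    A minimal, reproducible stand-in for artifact cleaning beyond the
    band-pass: any trial containing a sample with |x| above the threshold
    (default 100 µV — larger than plausible band-limited cortical EEG)
    is rejected outright.
    """
    keep = np.abs(ts.data).max(axis=(1, 2)) <= threshold_uv
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("rejected %d/%d trials above %.1f µV",
                    n_dropped, len(ts), threshold_uv)
    return ts[np.flatnonzero(keep)]


def baseline_correct(ts: TrialSet) -> TrialSet:
    """Subtract each channel's task-window mean (DC removal)."""
    data = ts.data - ts.data.mean(axis=2, keepdims=True)
    return TrialSet(data, ts.labels, ts.subjects, ts.blocks,
                    ts.montage, ts.sample_rate)


def zscore_trials(ts: TrialSet) -> TrialSet:
    """Per-trial, per-channel standardisation (classifier input conditioning)."""
    mean = ts.data.mean(axis=2, keepdims=True)
    sd = ts.data.std(axis=2, keepdims=True)
    data = (ts.data - mean) / np.maximum(sd, 1e-12)
    return TrialSet(data, ts.labels, ts.subjects, ts.blocks,
                    ts.montage, ts.sample_rate)


def split_trials(ts: TrialSet, train_proportion: float,
                 seed: int) -> tuple[TrialSet, TrialSet]:
    """Stratified train/test split, per subject AND per class.

    The training allocation totals ``round(train_proportion * len(ts))``
    exactly, distributed across (subject, class) strata by largest
    remainder with round-robin tie-breaking over classes so per-class
    counts deviate from ``proportion * class count`` by at most one per
    stratum.  Deterministic in (ts, proportion, seed).
    """
    if not (0.0 < train_proportion < 1.0):
        raise SplitError("train_proportion must be in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5F11]))

    strata: list[tuple[tuple[int, int], np.ndarray]] = []
    for sid in np.unique(ts.subjects):
        for label in np.unique(ts.labels):
            idx = np.flatnonzero((ts.subjects == sid) & (ts.labels == label))
            if len(idx):
                strata.append(((int(sid), int(label)), idx))

    total_target = round(train_proportion * len(ts))
    base = {key: int(np.floor(train_proportion * len(idx)))
            for key, idx in strata}
    remainder = total_target - sum(base.values())
    # distribute the remainder by largest fractional part, cycling over
    # classes so no verb is systematically favoured
    frac = sorted(strata,
                  key=lambda kv: -(train_proportion * len(kv[1]) - base[kv[0]]))
    classes = sorted({key[1] for key, _ in strata})
    by_class = {c: [kv for kv in frac if kv[0][1] == c] for c in classes}
    order: list[tuple[int, int]] = []
    i = 0
    while any(by_class[c] for c in classes):
        c = classes[i % len(classes)]
        if by_class[c]:
            order.append(by_class[c].pop(0)[0])
        i += 1
    for key in order[:max(remainder, 0)]:
        base[key] += 1

    train_idx, test_idx = [], []
    for key, idx in strata:
        n_train = base[key]
        if n_train == 0 or n_train == len(idx):
            raise SplitError(
                f"proportion {train_proportion} leaves an empty partition "
                f"for subject {key[0]}, class {key[1]} ({len(idx)} trials)")
        perm = rng.permutation(idx)
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])

    train_idx = np.sort(np.concatenate(train_idx))
    test_idx = np.sort(np.concatenate(test_idx))
    return ts[train_idx], ts[test_idx]
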