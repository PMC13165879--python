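"""Core data containers shared by every stage of the decoding pipeline.

The study design is a visually cued overt-speech task: 30 participants each
complete 5 blocks; within a block each of six Mandarin action verbs (Chi, He,
Chuan, Na, Kan, Dai) is prompted 15 times in random order, giving 75 trials
per verb per participant and 13,500 labelled 4-s EEG epochs in total.  Eight
electrodes over the left-hemisphere language areas (Broca: F5, FT7, FC5, FC3;
Wernicke: TP7, CP5, CP3, P5) are recorded at 250 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

#: The six Mandarin action verbs, in canonical label order 0..5.
CLASS_NAMES: tuple[str, ...] = ("Chi", "He", "Chuan", "Na", "Kan", "Dai")

#: Language-area electrode montage, in canonical row order.
DEFAULT_MONTAGE: tuple[str, ...] = (
    "F5", "FT7", "FC5", "FC3", "TP7", "CP5", "CP3", "P5",
)


class DimensionError(ValueError):
    """Array dimensions inconsistent with the experiment design."""


class MontageError(KeyError):
    """A requested channel label is absent from a recording."""


class SplitError(ValueError):
    """A stratified split would leave an empty class in one partition."""


@dataclass(frozen=True)
class ExperimentDesign:
    """Parameters of the acquisition protocol.

    Defaults reproduce the study: 30 subjects x 6 verbs x 75 trials, trials
    organised as 5 blocks of 15 randomised repetitions per verb, 8 channels
    at 250 Hz, and a 2 s idle / 1 s cue / 4 s task / 2 s rest trial timeline.
    """

    n_subjects: int = 30
    n_classes: int = 6
    trials_per_class: int = 75
    blocks: int = 5
    reps_per_block: int = 15
    n_channels: int = 8
    sample_rate: float = 250.0
    idle_s: float = 2.0
    cue_s: float = 1.0
    task_s: float = 4.0
    rest_s: float = 2.0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_classes", "trials_per_class",
                     "blocks", "reps_per_block", "n_channels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.blocks * self.reps_per_block != self.trials_per_class:
            raise ValueError(
                "blocks * reps_per_block must equal trials_per_class "
                f"({self.blocks} * {self.reps_per_block} != {self.trials_per_class})"
            )
        n = self.task_s * self.sample_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError("task_s * sample_rate must be an integer sample count")

    @property
    def n_task_samples(self) -> int:
        """Samples in one task-window epoch (1000 at the defaults)."""
        return round(self.task_s * self.sample_rate)

    @property
    def trials_per_subject(self) -> int:
        return self.n_classes * self.trials_per_class

    @property
    def n_trials_total(self) -> int:
        return self.n_subjects * self.trials_per_subject

    @property
    def trial_s(self) -> float:
        """Full trial duration including idle, cue and rest."""
        return self.idle_s + self.cue_s + self.task_s + self.rest_s


@dataclass(frozen=True)
class Event:
    """A timeline marker in a raw recording (0-based sample index)."""

    onset: int
    label: int
    kind: str  # idle | cue | stimulus | rest
    block: int = 0


@dataclass
class RawRecording:
    """A continuous multi-channel recording with its event timeline."""

    samples: np.ndarray  # (channels, time), microvolts
    channel_names: tuple[str, ...]
    sample_rate: float
    events: tuple[Event, ...] = ()
    subject_id: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.samples.ndim != 2:
            raise DimensionError("samples must be a channels x time matrix")
        if len(self.channel_names) != self.samples.shape[0]:
            raise DimensionError("channel_names length must match sample rows")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        onsets = [e.onset for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass(frozen=True)
class EpochedTrial:
    """One labelled task-window epoch."""

    data: np.ndarray  # (channels, time), microvolts
    label: int
    subject_id: int
    block_id: int


class TrialSet:
    """An ordered collection of equally shaped labelled epochs.

    Stored internally as a dense (n_trials, channels, time) array with
    parallel label / subject / block vectors; `trials` iterates as
    :class:`EpochedTrial` views.
    """

    def __init__(
        self,
        data: np.ndarray,
        labels: Sequence[int],
        subjects: Sequence[int],
        blocks: Sequence[int],
        montage: Sequence[str] = DEFAULT_MONTAGE,
        sample_rate: float = 250.0,
    ) -> None:
        self.data = np.asarray(data)
        self.labels = np.asarray(labels, dtype=int)
        self.subjects = np.asarray(subjects, dtype=int)
        self.blocks = np.asarray(blocks, dtype=int)
        self.montage = tuple(montage)
        self.sample_rate = float(sample_rate)
        n = self.data.shape[0]
        if self.data.ndim != 3:
            raise DimensionError("data must be (n_trials, channels, time)")
        if not (len(self.labels) == len(self.subjects) == len(self.blocks) == n):
            raise DimensionError("metadata vectors must match trial count")
        if self.data.shape[1] != len(self.montage):
            raise DimensionError("channel dimension must match montage length")

    def __len__(self) -> int:
        return self.data.shape[0]

    def __getitem__(self, idx) -> "TrialSet":
        idx = np.asarray(idx)
        return TrialSet(self.data[idx], self.labels[idx], self.subjects[idx],
                        self.blocks[idx], self.montage, self.sample_rate)

    @property
    def trials(self) -> Iterator[EpochedTrial]:
        for i in range(len(self)):
            yield EpochedTrial(self.data[i], int(self.labels[i]),
                               int(self.subjects[i]), int(self.blocks[i]))

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def for_subject(self, subject_id: int) -> "TrialSet":
        return self[np.flatnonzero(self.subjects == subject_id)]

    def for_class(self, label: int) -> "TrialSet":
        return self[np.flatnonzero(self.labels == label)]

    def concat(self, other: "TrialSet") -> "TrialSet":
        if other.montage != self.montage:
            raise DimensionError("cannot concatenate trial sets with different montages")
        return TrialSet(
            np.concatenate([self.data, other.data]),
            np.concatenate([self.labels, other.labels]),
            np.concatenate([self.subjects, other.subjects]),
            np.concatenate([self.blocks, other.blocks]),
            self.montage, self.sample_rate,
        )


# ---------------------------------------------------------------------------
# Dataset container I/O: one self-describing array file per subject plus a
# plain-text manifest (one row per trial: subject, block, class, file, index).
# ---------------------------------------------------------------------------

def save_dataset(ts: TrialSet, out_dir: str | Path) -> Path:
    """Write a trial set as per-subject ``.npz`` files + ``manifest.tsv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = ["subject\tblock\tclass\tfile\tindex"]
    for sid in np.unique(ts.subjects):
        sub = ts.for_subject(int(sid))
        fname = f"subject_{sid:03d}.npz"
        np.savez(
            out / fname,
            data=sub.data,
            labels=sub.labels,
            blocks=sub.blocks,
            channel_names=np.array(sub.montage),
            sample_rate=np.array(sub.sample_rate),
        )
        for i in range(len(sub)):
            rows.append(f"{sid}\t{sub.blocks[i]}\t{sub.labels[i]}\t{fname}\t{i}")
    (out / "manifest.tsv").write_text("\n".join(rows) + "\n")
    return out


def load_dataset(in_dir: str | Path) -> TrialSet:
    """Read a dataset written by :func:`save_dataset`."""
    in_dir = Path(in_dir)
    files = sorted(in_dir.glob("subject_*.npz"))
    if not files:
        raise FileNotFoundError(f"no subject_*.npz files in {in_dir}")
    parts = []
    for f in files:
        with np.load(f, allow_pickle=False) as z:
            sid = int(f.stem.split("_")[1])
            parts.append(TrialSet(
                z["data"], z["labels"], np.full(len(z["labels"]), sid),
                z["blocks"], tuple(z["channel_names"]), float(z["sample_rate"]),
            ))
    ts = parts[0]
    for p in parts[1:]:
        ts = ts.concat(p)
    return ts
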