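"""Synthetic EEG generator reproducing the verb-decoding study design.

Generates labelled multi-channel epochs with the acquisition protocol's exact
arithmetic (subjects x verbs x trials, randomised blocks) and controllable
class structure, so every downstream stage — filtering, CSP, the recurrent
decoder, the evaluation protocols — can be exercised without the real
recordings.

Signal model
------------
Each trial is the sum of three parts::

    trial = background(1/f) + artifacts + a * pattern (x) (envelope * carrier)

* ``background`` is per-channel 1/f ("pink") noise, the canonical EEG
  spectral shape.
* ``artifacts`` are ocular (slow frontal transients, <4 Hz), myogenic
  (>30 Hz bursts) and power-line (50 Hz) contamination — the artifact
  classes the acquisition targets for removal.
* the evoked component is a rank-one space-time outer product: a fixed
  unit-norm spatial topography ``pattern``, an amplitude ``envelope`` over
  the 4-s task window, and a fresh 8-30 Hz band-limited noise ``carrier``
  per trial.  The scale ``a`` realises a requested signal-to-background
  ratio in dB.

Class information can be placed in the spatial topographies (separable by
covariance methods such as CSP), in the temporal ordering of the envelope
(invisible to covariance methods, separable by a sequence model), or both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .containers import (
    DEFAULT_MONTAGE,
    DimensionError,
    Event,
    ExperimentDesign,
    RawRecording,
    TrialSet,
)

#: Background RMS amplitude in microvolts; typical scalp-EEG scale.
BACKGROUND_UV = 10.0

#: Carrier band (Hz): alpha + beta, inside the 4-45 Hz acquisition band.
CARRIER_BAND = (8.0, 30.0)


@dataclass(frozen=True)
class ClassSignature:
    """The evoked component of one verb class.

    ``spatial_pattern`` is a unit-norm forward-model topography over
    channels; ``temporal_envelope`` is a nonnegative amplitude profile over
    the task window; ``snr_db`` scales evoked power relative to the 1/f
    background (``-inf`` disables the evoked component entirely).
    """

    spatial_pattern: np.ndarray
    temporal_envelope: np.ndarray
    snr_db: float = 0.0

    def __post_init__(self) -> None:
        p = np.asarray(self.spatial_pattern, dtype=float)
        e = np.asarray(self.temporal_envelope, dtype=float)
        if not np.isclose(np.linalg.norm(p), 1.0, atol=1e-8):
            raise ValueError("spatial_pattern must have unit Euclidean norm")
        if np.any(e < 0):
            raise ValueError("temporal_envelope must be nonnegative")
        object.__setattr__(self, "spatial_pattern", p)
        object.__setattr__(self, "temporal_envelope", e)


@dataclass(frozen=True)
class NoiseModel:
    """Background and artifact generator parameters.

    ``one_over_f_exponent`` is the background spectral slope (power ~
    1/f^exponent); artifact amplitudes are in microvolts and rates in
    events per minute.
    """

    one_over_f_exponent: float = 1.0
    line_freq: float = 50.0
    eog_rate: float = 4.0       # blinks/min
    emg_band: tuple[float, float] = (30.0, 100.0)
    emg_rate: float = 2.0       # bursts/min
    eog_amp_uv: float = 60.0
    emg_amp_uv: float = 15.0
    line_amp_uv: float = 2.0

    def __post_init__(self) -> None:
        if self.one_over_f_exponent < 0:
            raise ValueError("one_over_f_exponent must be >= 0")
        if self.line_freq not in (50.0, 60.0):
            raise ValueError("line_freq must be 50 or 60 Hz")

    @classmethod
    def quiet(cls, one_over_f_exponent: float = 1.0) -> "NoiseModel":
        """Background only: no ocular, myogenic or line contamination."""
        return cls(one_over_f_exponent=one_over_f_exponent,
                   eog_rate=0.0, emg_rate=0.0, line_amp_uv=0.0)


# ---------------------------------------------------------------------------
# Component generators
# ---------------------------------------------------------------------------

def one_over_f_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                     exponent: float) -> np.ndarray:
    """Unit-RMS per-channel noise with power spectrum ~ 1/f^exponent."""
    white = rng.standard_normal((n_channels, n_samples))
    if exponent == 0:
        return white
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samples)
    f[0] = f[1]  # keep DC finite; removed again by standardisation
    spec *= f ** (-exponent / 2.0)
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    x -= x.mean(axis=1, keepdims=True)
    rms = np.sqrt((x ** 2).mean(axis=1, keepdims=True))
    return x / np.maximum(rms, 1e-30)


def bandlimited_carrier(rng: np.random.Generator, n_samples: int,
                        sample_rate: float,
                        band: tuple[float, float] = CARRIER_BAND) -> np.ndarray:
    """Unit-variance noise confined to ``band`` (default 8-30 Hz)."""
    sos = sps.butter(4, band, btype="bandpass", fs=sample_rate, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n_samples))
    sd = x.std()
    return x / max(sd, 1e-30)


def _artifacts(rng: np.random.Generator, noise: NoiseModel, n_channels: int,
               n_samples: int, sample_rate: float,
               frontal_weight: np.ndarray) -> np.ndarray:
    """Ocular transients + myogenic bursts + line interference, in microvolts."""
    out = np.zeros((n_channels, n_samples))
    dur_min = n_samples / sample_rate / 60.0

    n_eog = rng.poisson(noise.eog_rate * dur_min)
    blink_len = round(0.4 * sample_rate)
    blink = np.hanning(blink_len)  # slow (<4 Hz) raised-cosine deflection
    for _ in range(n_eog):
        t0 = rng.integers(0, max(1, n_samples - blink_len))
        amp = noise.eog_amp_uv * rng.uniform(0.6, 1.4) * rng.choice([-1.0, 1.0])
        out[:, t0:t0 + blink_len] += amp * np.outer(frontal_weight, blink)

    n_emg = rng.poisson(noise.emg_rate * dur_min)
    burst_len = round(0.25 * sample_rate)
    if n_emg and burst_len > 18:  # need enough samples for a stable high-pass
        lo = min(noise.emg_band[0], 0.45 * sample_rate)
        sos = sps.butter(4, lo, btype="highpass", fs=sample_rate, output="sos")
        for _ in range(n_emg):
            t0 = rng.integers(0, max(1, n_samples - burst_len))
            ch = rng.integers(0, n_channels)
            burst = sps.sosfiltfilt(sos, rng.standard_normal(burst_len))
            burst *= np.hanning(burst_len)
            out[ch, t0:t0 + burst_len] += noise.emg_amp_uv * burst

    if noise.line_amp_uv > 0:
        t = np.arange(n_samples) / sample_rate
        phase = rng.uniform(0, 2 * np.pi)
        out += noise.line_amp_uv * np.sin(2 * np.pi * noise.line_freq * t + phase)
    return out


def _frontal_weight(montage: tuple[str, ...]) -> np.ndarray:
    """Ocular artifacts load frontal channels most strongly."""
    frontal = {"F5", "FT7", "FC5", "FC3"}
    return np.array([1.0 if name in frontal else 0.25 for name in montage])


def _synth_trial(rng: np.random.Generator, sig: ClassSignature,
                 noise: NoiseModel, design: ExperimentDesign,
                 frontal_weight: np.ndarray) -> np.ndarray:
    n, t = design.n_channels, design.n_task_samples
    bg = BACKGROUND_UV * one_over_f_noise(rng, n, t, noise.one_over_f_exponent)
    trial = bg + _artifacts(rng, noise, n, t, design.sample_rate, frontal_weight)
    if np.isfinite(sig.snr_db):
        carrier = bandlimited_carrier(rng, t, design.sample_rate)
        evoked = np.outer(sig.spatial_pattern, sig.temporal_envelope * carrier)
        p_ev = (evoked ** 2).mean()
        if p_ev > 0:
            p_bg = (bg ** 2).mean()
            scale = np.sqrt(10.0 ** (sig.snr_db / 10.0) * p_bg / p_ev)
            trial += scale * evoked
    return trial


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def _block_orders(rng: np.random.Generator,
                  design: ExperimentDesign) -> list[np.ndarray]:
    """Class order per block: each verb repeated reps_per_block times, shuffled."""
    base = np.repeat(np.arange(design.n_classes), design.reps_per_block)
    return [rng.permutation(base) for _ in range(design.blocks)]


def generate_dataset(design: ExperimentDesign,
                     signatures: list[ClassSignature],
                     noise: NoiseModel,
                     seed: int,
                     dtype=np.float64) -> TrialSet:
    """Synthesize the full labelled epoch set for a design.

    Returns ``n_subjects * n_classes * trials_per_class`` task-window epochs
    of shape (n_channels, task samples), with class order randomised within
    each block of repetitions.  Deterministic in (parameters, seed).
    """
    if len(signatures) != design.n_classes:
        raise DimensionError(
            f"need one signature per class: got {len(signatures)} "
            f"for {design.n_classes} classes")
    for s in signatures:
        if len(s.spatial_pattern) != design.n_channels:
            raise DimensionError("spatial_pattern length must equal n_channels")
        if len(s.temporal_envelope) != design.n_task_samples:
            raise DimensionError(
                "temporal_envelope length must equal task_s * sample_rate")

    montage = tuple(DEFAULT_MONTAGE[:design.n_channels]) \
        if design.n_channels <= len(DEFAULT_MONTAGE) \
        else tuple(f"CH{i}" for i in range(design.n_channels))
    fw = _frontal_weight(montage)

    n_total = design.n_trials_total
    data = np.empty((n_total, design.n_channels, design.n_task_samples),
                    dtype=dtype)
    labels = np.empty(n_total, dtype=int)
    subjects = np.empty(n_total, dtype=int)
    blocks = np.empty(n_total, dtype=int)

    i = 0
    root = np.random.SeedSequence([int(seed), 0x5EED])
    for sid, ss in enumerate(root.spawn(design.n_subjects)):
        rng = np.random.default_rng(ss)
        for b, order in enumerate(_block_orders(rng, design)):
            for label in order:
                data[i] = _synth_trial(rng, signatures[label], noise, design, fw)
                labels[i], subjects[i], blocks[i] = label, sid, b
                i += 1
    return TrialSet(data, labels, subjects, blocks, montage, design.sample_rate)


def generate_recording(design: ExperimentDesign,
                       signatures: list[ClassSignature],
                       noise: NoiseModel,
                       seed: int,
                       subject_id: int = 0) -> RawRecording:
    """Synthesize one subject's full continuous recording with events.

    The timeline follows the trial sequence idle / cue / stimulus (task) /
    rest; evoked components are inserted only in task windows.  Intended
    for epoching and end-to-end preprocessing tests.
    """
    if len(signatures) != design.n_classes:
        raise DimensionError("need one signature per class")
    montage = tuple(DEFAULT_MONTAGE[:design.n_channels]) \
        if design.n_channels <= len(DEFAULT_MONTAGE) \
        else tuple(f"CH{i}" for i in range(design.n_channels))
    fw = _frontal_weight(montage)
    fs = design.sample_rate
    trial_len = round(design.trial_s * fs)
    n_trials = design.trials_per_subject
    n_samples = trial_len * n_trials

    root = np.random.SeedSequence([int(seed), 0x7EC, int(subject_id)])
    rng = np.random.default_rng(root)
    samples = BACKGROUND_UV * one_over_f_noise(
        rng, design.n_channels, n_samples, noise.one_over_f_exponent)
    samples += _artifacts(rng, noise, design.n_channels, n_samples, fs, fw)

    idle_n = round(design.idle_s * fs)
    cue_n = round(design.cue_s * fs)
    task_n = design.n_task_samples
    events: list[Event] = []
    t0 = 0
    for b, order in enumerate(_block_orders(rng, design)):
        for label in order:
            on = t0 + idle_n + cue_n
            events.append(Event(t0, int(label), "idle", b))
            events.append(Event(t0 + idle_n, int(label), "cue", b))
            events.append(Event(on, int(label), "stimulus", b))
            events.append(Event(on + task_n, int(label), "rest", b))
            sig = signatures[label]
            if np.isfinite(sig.snr_db):
                carrier = bandlimited_carrier(rng, task_n, fs)
                evoked = np.outer(sig.spatial_pattern,
                                  sig.temporal_envelope * carrier)
                p_ev = (evoked ** 2).mean()
                if p_ev > 0:
                    scale = np.sqrt(10.0 ** (sig.snr_db / 10.0)
                                    * BACKGROUND_UV ** 2 / p_ev)
                    samples[:, on:on + task_n] += scale * evoked
            t0 += trial_len
    return RawRecording(samples, montage, fs, tuple(events), subject_id)


# ---------------------------------------------------------------------------
# Scenario factories: where the class information lives
# ---------------------------------------------------------------------------

def make_spatial_scenario(separation: float, seed: int,
                          n_classes: int = 6, n_channels: int = 8,
                          n_task_samples: int = 1000,
                          snr_db: float = 0.0) -> list[ClassSignature]:
    """Class-distinct spatial topographies, shared flat envelope.

    Patterns are ``normalize(u0 + separation * v_k)`` with ``u0`` a common
    random direction and ``v_k`` mutually orthonormal directions orthogonal
    to ``u0``: at separation 0 all classes share one topography; pairwise
    angles grow with separation (pairwise cosine = 1 / (1 + separation^2)).
    Covariance methods (CSP) separate this scenario.
    """
    if separation < 0:
        raise ValueError("separation must be >= 0")
    if n_classes + 1 > n_channels:
        raise DimensionError("need n_channels > n_classes for orthogonal offsets")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x59A]))
    basis, _ = np.linalg.qr(rng.standard_normal((n_channels, n_classes + 1)))
    u0, offsets = basis[:, 0], basis[:, 1:]
    env = np.ones(n_task_samples)
    sigs = []
    for k in range(n_classes):
        p = u0 + separation * offsets[:, k]
        sigs.append(ClassSignature(p / np.linalg.norm(p), env, snr_db))
    return sigs


#: Segment amplitude profile shared by every class in the temporal scenario;
#: classes differ only in its cyclic order.
TEMPORAL_BASE_AMPLITUDES = (2.0, 0.0, 1.0, 0.0, 1.5, 0.5)


def make_temporal_scenario(seed: int, n_classes: int = 6, n_channels: int = 8,
                           n_task_samples: int = 1000,
                           snr_db: float = 20.0) -> list[ClassSignature]:
    """Identical topography and covariance; class-distinct envelope order.

    Every class shares one spatial pattern and one multiset of envelope
    segment amplitudes; class k uses the k-th cyclic shift of the segment
    sequence.  Because time-averaged envelope power is order-invariant, the
    expected channel covariance is identical across classes — static
    variance features (CSP) carry no class information, while the temporal
    ordering remains fully class-discriminative for a sequence model.
    """
    if n_classes > len(TEMPORAL_BASE_AMPLITUDES):
        raise DimensionError("at most one class per envelope segment")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x7E3]))
    p = rng.standard_normal(n_channels)
    p = np.abs(p) + 0.5          # same-sign topography, away from zero
    p /= np.linalg.norm(p)

    n_seg = len(TEMPORAL_BASE_AMPLITUDES)
    seg_len = int(np.ceil(n_task_samples / n_seg))
    base = np.repeat(TEMPORAL_BASE_AMPLITUDES, seg_len)[:n_task_samples]
    # circular smoothing commutes with the cyclic shift, so every class
    # envelope stays an exact rotation of the same sequence
    kernel = np.hanning(round(0.1 * n_task_samples) | 1)
    kernel /= kernel.sum()
    smooth = np.real(np.fft.ifft(np.fft.fft(base) * np.fft.fft(kernel, n_task_samples)))
    smooth = np.clip(smooth, 0.0, None)
    shift = n_task_samples // n_seg
    return [ClassSignature(p, np.roll(smooth, k * shift), snr_db)
            for k in range(n_classes)]


def make_mixed_scenario(separation: float, seed: int, n_classes: int = 6,
                        n_channels: int = 8, n_task_samples: int = 1000,
                        snr_db: float = 5.0) -> list[ClassSignature]:
    """Both spatial and temporal class structure (the realistic case)."""
    spatial = make_spatial_scenario(separation, seed, n_classes, n_channels,
                                    n_task_samples, snr_db)
    temporal = make_temporal_scenario(seed, n_classes, n_channels,
                                      n_task_samples, snr_db)
    return [ClassSignature(s.spatial_pattern, t.temporal_envelope, snr_db)
            for s, t in zip(spatial, temporal)]
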