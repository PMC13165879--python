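"""Mel-Frequency Cepstral Coefficient reference features for the spoken verbs.

The spoken recordings (24 kHz mono, time-aligned with the EEG) are reduced
to 13 cepstral coefficients per frame through the canonical six-stage
pipeline: pre-emphasis, framing, windowing, FFT power spectrum, mel filter
bank, and discrete cosine transform.  MFCCs serve as a reference acoustic
representation stored alongside trials; the decoders' training loss is
label cross-entropy, with MFCC regression available only as an explicitly
flagged auxiliary target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.fft import dct
from scipy.io import wavfile


@dataclass(frozen=True)
class AudioSegment:
    """Mono audio at a known rate (24 kHz in the study)."""

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples",
                           np.asarray(self.samples, dtype=float).ravel())


@dataclass(frozen=True)
class MfccConfig:
    """Canonical MFCC settings (all exposed; none are study-specific)."""

    frame_length_s: float = 0.025
    frame_step_s: float = 0.010
    pre_emphasis: float = 0.97
    n_filters: int = 26
    n_coeffs: int = 13
    fft_size: int | None = None   # default: next power of two >= frame length
    f_low: float = 0.0
    f_high: float | None = None   # default: Nyquist
    log_floor: float = 1e-10


@dataclass(frozen=True)
class MfccMatrix:
    coeffs: np.ndarray  # (frames, n_coeffs)
    frame_length_s: float
    frame_step_s: float


def hz_to_mel(f):
    """Standard mel map 2595 log10(1 + f/700)."""
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(n_filters: int, fft_size: int, sample_rate: float,
                   f_low: float = 0.0,
                   f_high: float | None = None) -> np.ndarray:
    """Triangular filters equally spaced on the mel scale.

    Returns an (n_filters, fft_size // 2 + 1) nonnegative weight matrix.
    """
    if f_high is None:
        f_high = sample_rate / 2.0
    if f_high > sample_rate / 2.0:
        raise ValueError("f_high exceeds Nyquist")
    edges_hz = mel_to_hz(np.linspace(hz_to_mel(f_low), hz_to_mel(f_high),
                                     n_filters + 2))
    bins = np.floor((fft_size + 1) * edges_hz / sample_rate).astype(int)
    if np.any(np.diff(bins[1:-1]) < 1):
        raise ValueError(
            f"{n_filters} filters cannot be resolved with fft_size={fft_size} "
            f"at {sample_rate} Hz: adjacent filter peaks collide")
    fb = np.zeros((n_filters, fft_size // 2 + 1))
    for k in range(n_filters):
        left, center, right = bins[k], bins[k + 1], bins[k + 2]
        for b in range(left, center):
            fb[k, b] = (b - left) / max(center - left, 1)
        for b in range(center, right):
            fb[k, b] = (right - b) / max(right - center, 1)
    return fb


def frame_signal(x: np.ndarray, frame_len: int, step: int) -> np.ndarray:
    """Overlapping analysis frames; count = floor((n - len)/step) + 1."""
    n_frames = (len(x) - frame_len) // step + 1
    if n_frames < 1:
        return np.empty((0, frame_len))
    idx = np.arange(frame_len)[None, :] + step * np.arange(n_frames)[:, None]
    return x[idx]


def mfcc_extract(audio: AudioSegment,
                 config: MfccConfig = MfccConfig()) -> MfccMatrix:
    """Run the six-stage cepstral pipeline on one audio segment."""
    sr = audio.sample_rate
    frame_len = round(config.frame_length_s * sr)
    step = round(config.frame_step_s * sr)
    if len(audio.samples) < frame_len:
        warnings.warn("audio shorter than one frame; empty MFCC matrix",
                      stacklevel=2)
        return MfccMatrix(np.empty((0, config.n_coeffs)),
                          config.frame_length_s, config.frame_step_s)

    # 1. pre-emphasis
    x = np.append(audio.samples[0],
                  audio.samples[1:] - config.pre_emphasis * audio.samples[:-1])
    # 2. framing
    frames = frame_signal(x, frame_len, step)
    # 3. windowing (Hamming)
    frames = frames * np.hamming(frame_len)
    # 4. FFT power spectrum
    fft_size = config.fft_size or int(2 ** np.ceil(np.log2(frame_len)))
    power = np.abs(np.fft.rfft(frames, n=fft_size, axis=1)) ** 2 / fft_size
    # 5. mel filter bank + log
    fb = mel_filterbank(config.n_filters, fft_size, sr,
                        config.f_low, config.f_high)
    energies = np.log(np.maximum(power @ fb.T, config.log_floor))
    # 6. DCT, keep the first n_coeffs cepstral coefficients
    cepstra = dct(energies, type=2, norm="ortho", axis=1)[:, :config.n_coeffs]
    return MfccMatrix(cepstra, config.frame_length_s, config.frame_step_s)


def read_wav(path) -> AudioSegment:
    """Read a PCM WAV file as mono float audio."""
    sr, raw = wavfile.read(path)
    data = np.asarray(raw, dtype=float)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(raw.dtype, np.integer):
        data = data / np.iinfo(raw.dtype).max
    return AudioSegment(data, float(sr))
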