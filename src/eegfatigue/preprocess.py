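"""Denoising, band-pass filtering, downsampling, epoching and labelling.

The preprocessing chain mirrors standard drowsiness-EEG practice: wavelet
soft-threshold denoising (blink and muscle transients are low-frequency,
mains pickup high-frequency), a 1-75 Hz zero-phase band-pass, downsampling
to 200 Hz, truncation into non-overlapping 60 s epochs, and labelling of
each epoch from the most recent Karolinska Sleepiness Scale (KSS) rating:

    KSS 1-5 -> normal, 6-8 -> critical, 9 -> fatigue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pywt
from scipy import signal as sps

from .errors import ConfigurationError, InputError

__all__ = [
    "PreprocessConfig",
    "RawRecording",
    "Epoch",
    "STATES",
    "label_from_kss",
    "denoise",
    "bandpass_downsample",
    "make_epochs",
    "preprocess_recording",
]

STATES = ("normal", "critical", "fatigue")
STATE_TO_INDEX = {s: i for i, s in enumerate(STATES)}


@dataclass
class PreprocessConfig:
    wavelet_name: str = "db4"
    decomposition_levels: int = 5
    band_low: float = 1.0
    band_high: float = 75.0
    target_fs: float = 200.0
    epoch_length: float = 60.0
    filter_order: int = 4

    def __post_init__(self) -> None:
        if not (0 < self.band_low < self.band_high < self.target_fs / 2):
            raise ConfigurationError(
                "need 0 < band_low < band_high < target_fs/2, got "
                f"{self.band_low}, {self.band_high}, {self.target_fs}"
            )
        if self.epoch_length <= 0:
            raise ConfigurationError("epoch_length must be positive")
        if self.decomposition_levels < 1:
            raise ConfigurationError("decomposition_levels must be >= 1")


@dataclass
class RawRecording:
    """Multichannel time series with channel labels and a KSS timeline."""

    samples: np.ndarray  # channels x time
    channel_labels: list
    fs: float
    kss_timeline: list = field(default_factory=list)  # [(offset_s, kss)]
    subject_id: str = "unknown"
    state: str | None = None  # ground-truth state for simulated data

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise InputError("samples must be a channels x time matrix")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise InputError(
                f"{len(self.channel_labels)} labels for "
                f"{self.samples.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise InputError("channel labels must be unique")
        if not self.fs > 0:
            raise InputError("sampling rate must be positive")
        offsets = [t for t, _ in self.kss_timeline]
        if any(b <= a for a, b in zip(offsets, offsets[1:])):
            raise InputError("KSS timeline offsets must be strictly increasing")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.fs


@dataclass
class Epoch:
    """One fixed-length labelled analysis window."""

    samples: np.ndarray  # channels x time, at the epoch's fs
    state: str
    kss: int
    subject_id: str
    start_time: float
    fs: float
    channel_labels: list

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.state not in STATES:
            raise InputError(f"unknown state {self.state!r}")


def label_from_kss(kss: int) -> str:
    """Map a KSS rating (1-9) to the three-state label."""
    if not (isinstance(kss, (int, np.integer)) and 1 <= kss <= 9):
        raise InputError(f"KSS rating must be an integer in 1..9, got {kss!r}")
    if kss <= 5:
        return "normal"
    if kss <= 8:
        return "critical"
    return "fatigue"


def denoise(recording: RawRecording, config: PreprocessConfig | None = None
            ) -> RawRecording:
    """Wavelet soft-threshold denoising, channel by channel.

    Decomposes with the configured wavelet, estimates the noise scale from
    the finest-level detail coefficients (median absolute deviation /
    0.6745), applies the universal threshold sqrt(2 ln n) * sigma softly to
    all detail levels, and reconstructs.
    """
    config = config or PreprocessConfig()
    x = recording.samples
    n = x.shape[1]
    if n < 2 ** config.decomposition_levels:
        raise InputError(
            f"recording of {n} samples too short for "
            f"{config.decomposition_levels} decomposition levels"
        )
    coeffs = pywt.wavedec(x, config.wavelet_name,
                          level=config.decomposition_levels, axis=-1)
    finest = coeffs[-1]
    sigma = np.median(np.abs(finest), axis=-1, keepdims=True) / 0.6745
    thr = sigma * np.sqrt(2.0 * np.log(n))
    den = [coeffs[0]] + [
        np.sign(d) * np.maximum(np.abs(d) - thr, 0.0) for d in coeffs[1:]
    ]
    y = pywt.waverec(den, config.wavelet_name, axis=-1)[:, :n]
    return RawRecording(y, list(recording.channel_labels), recording.fs,
                        list(recording.kss_timeline), recording.subject_id,
                        recording.state)


def bandpass_downsample(recording: RawRecording,
                        config: PreprocessConfig | None = None) -> RawRecording:
    """Zero-phase Butterworth band-pass, then rational resampling.

    The output is trimmed to round(n * target_fs / fs) samples so the
    length contract holds for any input length.
    """
    config = config or PreprocessConfig()
    fs = recording.fs
    if fs < 2 * config.band_high:
        raise ConfigurationError(
            f"sampling rate {fs} Hz cannot represent the "
            f"{config.band_high} Hz band edge"
        )
    sos = sps.butter(config.filter_order,
                     [config.band_low, config.band_high],
                     btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, recording.samples, axis=-1)

    ratio = (Fraction(config.target_fs).limit_denominator(10 ** 6)
             / Fraction(fs).limit_denominator(10 ** 6))
    if ratio != 1:
        y = sps.resample_poly(y, ratio.numerator, ratio.denominator, axis=-1)
    n_out = int(round(recording.samples.shape[1] * config.target_fs / fs))
    y = np.ascontiguousarray(y[:, :n_out])
    return RawRecording(y, list(recording.channel_labels), config.target_fs,
                        list(recording.kss_timeline), recording.subject_id,
                        recording.state)


def make_epochs(recording: RawRecording,
                config: PreprocessConfig | None = None) -> list[Epoch]:
    """Cut a recording into consecutive non-overlapping labelled epochs.

    A trailing partial window is discarded.  Each epoch inherits the most
    recent KSS rating at or before its start time (carry-forward).
    """
    config = config or PreprocessConfig()
    win = int(round(config.epoch_length * recording.fs))
    n = recording.samples.shape[1]
    n_epochs = n // win
    epochs: list[Epoch] = []
    timeline = sorted(recording.kss_timeline)
    for i in range(n_epochs):
        start = i * config.epoch_length
        kss = None
        for t, rating in timeline:
            if t <= start:
                kss = rating
            else:
                break
        if kss is None:
            raise InputError(
                f"no KSS rating at or before epoch start {start} s"
            )
        epochs.append(Epoch(
            samples=recording.samples[:, i * win:(i + 1) * win],
            state=label_from_kss(int(kss)),
            kss=int(kss),
            subject_id=recording.subject_id,
            start_time=start,
            fs=recording.fs,
            channel_labels=list(recording.channel_labels),
        ))
    return epochs


def preprocess_recording(recording: RawRecording,
                         config: PreprocessConfig | None = None,
                         apply_denoise: bool = True) -> list[Epoch]:
    """Full chain: denoise -> band-pass/downsample -> epochs."""
    config = config or PreprocessConfig()
    rec = denoise(recording, config) if apply_denoise else recording
    rec = bandpass_downsample(rec, config)
    return make_epochs(rec, config)
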