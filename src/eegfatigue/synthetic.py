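"""Synthetic 32-channel EEG with state-dependent band-power structure.

Each channel is a sum of band-limited noise components — white noise passed
through 4th-order zero-phase Butterworth band-pass filters, one per EEG band
(delta 1-4, theta 4-7, alpha 8-13, beta 14-30 Hz) — scaled by per-state
gains, plus broadband noise, blink transients on the frontal channels and
50 Hz mains pickup.  The shipped state profiles encode the qualitative
physiology of fatigue: delta and theta power rise, alpha falls, beta is
unchanged.  The gain magnitudes are synthetic conventions (real data fix
only the direction of the effects):

    state      delta  theta  alpha  beta
    normal     1.0    1.0    1.0    1.0
    critical   1.3    1.4    0.85   1.0
    fatigue    1.7    1.9    0.6    1.0

The delta gains are deliberately close to theta's: because RPSD is a power
*share*, the fatigue-state rise of the total-band denominator (driven by
theta) would otherwise swallow a small absolute delta increase and the
relative delta power would not rise, contradicting the fatigue signature
the profiles exist to emulate.

A Karolinska Sleepiness Scale rating consistent with the state is attached
every 10 minutes (normal -> 1-5, critical -> 6-8, fatigue -> 9).  All
randomness flows from a single integer seed: identical arguments and seed
give bitwise-identical recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError, InputError
from .preprocess import Epoch, RawRecording, STATES
from .topomap import CHANNEL_NAMES

__all__ = [
    "StateProfile",
    "GENERATION_BANDS",
    "KSS_RANGES",
    "BLINK_CHANNELS",
    "default_profiles",
    "generate_recording",
    "generate_dataset",
    "pure_tone_recording",
]

#: Band-pass edges used by the generator, Hz.  Delta starts at 1 Hz so the
#: generated spectrum matches what survives the 1-75 Hz preprocessing filter.
GENERATION_BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 13.0),
    "beta": (14.0, 30.0),
}

#: Base component amplitude per band (microvolt-scale standard deviation
#: before the state gain), loosely following the 1/f shape of resting EEG.
BASE_AMPLITUDES = {"delta": 4.0, "theta": 3.0, "alpha": 3.0, "beta": 1.5}

KSS_RANGES = {"normal": (1, 5), "critical": (6, 8), "fatigue": (9, 9)}

#: Anterior-posterior tilt of the state effects: fatigue-related delta/theta
#: increases are fronto-central, the alpha suppression is occipital (as in
#: drowsiness EEG).  The effective per-channel gain is
#: 1 + (gain - 1) * (1 + tilt * y), with y the channel's normalised
#: front-back coordinate, so the per-band scalp-mean effect keeps the
#: profile's direction while the topography becomes state-dependent.
SPATIAL_TILT = {"delta": 0.5, "theta": 0.6, "alpha": -0.6, "beta": 0.0}

#: Frontal channels that receive blink transients.
BLINK_CHANNELS = ("Fp1", "Fp2", "AF3", "AF4")

KSS_INTERVAL = 600.0  # seconds between ratings
MIN_DURATION = 60.0


@dataclass
class StateProfile:
    """Generation parameters for one fatigue state."""

    state: str
    band_gains: dict
    noise_sd: float = 1.0          # broadband noise amplitude, signal units
    blink_rate: float = 15.0       # blink events per minute
    line_amplitude: float = 0.5    # 50 Hz mains amplitude, signal units
    line_freq: float = 50.0

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise InputError(f"unknown state {self.state!r}")
        unknown = set(self.band_gains) - set(GENERATION_BANDS)
        if unknown:
            raise ConfigurationError(
                f"unknown band name(s) in profile: {sorted(unknown)}"
            )
        if any(g <= 0 for g in self.band_gains.values()):
            raise ConfigurationError("band gains must be strictly positive")
        if self.blink_rate < 0:
            raise ConfigurationError("blink rate must be >= 0")


_DEFAULT_GAINS = {
    "normal":   {"delta": 1.0, "theta": 1.0, "alpha": 1.0,  "beta": 1.0},
    "critical": {"delta": 1.3, "theta": 1.4, "alpha": 0.85, "beta": 1.0},
    "fatigue":  {"delta": 1.7, "theta": 1.9, "alpha": 0.6,  "beta": 1.0},
}


def default_profiles() -> dict:
    """The three shipped state profiles."""
    return {s: StateProfile(state=s, band_gains=dict(_DEFAULT_GAINS[s]))
            for s in STATES}


def _band_components(rng: np.random.Generator, band: tuple, shape: tuple,
                     fs: float) -> np.ndarray:
    """Unit-variance band-limited noise, one row per channel.

    The noise is generated with a margin of several filter time constants on
    each side and trimmed after filtering, so the slow edge transients of the
    low-frequency bands never reach the returned samples.
    """
    low, high = band
    pad = int(round(4 * fs / low))
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    padded = rng.standard_normal(shape[:-1] + (shape[-1] + 2 * pad,))
    x = sps.sosfiltfilt(sos, padded, axis=-1)[..., pad:pad + shape[-1]]
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def generate_recording(profile: StateProfile, duration: float = MIN_DURATION,
                       fs: float = 500.0, seed: int = 0,
                       subject_id: str | None = None) -> RawRecording:
    """Generate one 32-channel recording for the given state profile.

    duration is in seconds (>= 60); fs in Hz (>= 200).  The same profile,
    arguments and seed always produce bitwise-identical samples.
    """
    if duration < MIN_DURATION:
        raise InputError(f"duration must be >= {MIN_DURATION} s, got {duration}")
    if fs < 200:
        raise InputError(f"sampling rate must be >= 200 Hz, got {fs}")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    n_ch = len(CHANNEL_NAMES)
    samples = np.zeros((n_ch, n))

    background_sd = np.sqrt(sum(
        (BASE_AMPLITUDES[b] * profile.band_gains.get(b, 1.0)) ** 2
        for b in GENERATION_BANDS
    ) + profile.noise_sd ** 2)

    from .topomap import standard_montage
    y_coord = standard_montage().points3d[:, 1]  # front positive, in [-1, 1]

    for band, edges in GENERATION_BANDS.items():
        gain = profile.band_gains.get(band, 1.0)
        tilt = SPATIAL_TILT.get(band, 0.0)
        eff = 1.0 + (gain - 1.0) * (1.0 + tilt * y_coord)
        eff = np.maximum(eff, 0.05)
        samples += (BASE_AMPLITUDES[band] * eff[:, None]
                    * _band_components(rng, edges, (n_ch, n), fs))
    samples += profile.noise_sd * rng.standard_normal((n_ch, n))

    # blink artifacts: raised-cosine transients on the frontal channels
    n_blinks = rng.poisson(profile.blink_rate * duration / 60.0)
    blink_idx = [CHANNEL_NAMES.index(c) for c in BLINK_CHANNELS]
    for _ in range(n_blinks):
        width = rng.uniform(0.3, 0.5)
        center = rng.uniform(0, duration)
        w = int(round(width * fs))
        start = int(round(center * fs)) - w // 2
        lo, hi = max(start, 0), min(start + w, n)
        if hi <= lo:
            continue
        t = np.arange(lo - start, hi - start)
        pulse = 0.5 * (1 - np.cos(2 * np.pi * t / max(w - 1, 1)))
        samples[blink_idx, lo:hi] += 5.0 * background_sd * pulse

    if profile.line_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        t = np.arange(n) / fs
        samples += profile.line_amplitude * np.sin(
            2 * np.pi * profile.line_freq * t + phase)

    timeline = []
    t = 0.0
    lo, hi = KSS_RANGES[profile.state]
    while t < duration:
        timeline.append((t, int(rng.integers(lo, hi + 1))))
        t += KSS_INTERVAL

    return RawRecording(
        samples=samples,
        channel_labels=list(CHANNEL_NAMES),
        fs=fs,
        kss_timeline=timeline,
        subject_id=subject_id or f"sim-{profile.state}-{seed}",
        state=profile.state,
    )


def iter_dataset(counts: dict, fs: float = 500.0, seed: int = 0,
                 profiles: dict | None = None,
                 epoch_length: float = 60.0):
    """Lazily generate labelled raw epochs in the requested per-state counts.

    Per-epoch seeds derive deterministically from the master seed, so the
    same call always yields the same label sequence and samples.  Laziness
    keeps memory flat when building large corpora (a raw 60 s epoch is
    several megabytes).
    """
    profiles = profiles or default_profiles()
    for state_index, state in enumerate(STATES):
        count = int(counts.get(state, 0))
        if count < 0:
            raise InputError(f"negative epoch count for state {state!r}")
        for i in range(count):
            child = int(np.random.SeedSequence(
                [seed, state_index, i]).generate_state(1)[0] % (2 ** 31))
            rec = generate_recording(
                profiles[state], duration=epoch_length, fs=fs, seed=child,
                subject_id=f"sim-{state}-{i:04d}",
            )
            kss = rec.kss_timeline[0][1]
            yield Epoch(
                samples=rec.samples,
                state=state,
                kss=kss,
                subject_id=rec.subject_id,
                start_time=0.0,
                fs=fs,
                channel_labels=list(rec.channel_labels),
            )


def generate_dataset(counts: dict, fs: float = 500.0, seed: int = 0,
                     profiles: dict | None = None,
                     epoch_length: float = 60.0) -> list[Epoch]:
    """Materialised form of :func:`iter_dataset` (raw epochs at ``fs``)."""
    return list(iter_dataset(counts, fs=fs, seed=seed, profiles=profiles,
                             epoch_length=epoch_length))


def pure_tone_recording(freq: float = 10.0, duration: float = MIN_DURATION,
                        fs: float = 500.0, amplitude: float = 10.0,
                        kss: int = 1) -> RawRecording:
    """A noiseless single-frequency recording, handy for spectral checks."""
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    tone = amplitude * np.sin(2 * np.pi * freq * t)
    return RawRecording(
        samples=np.tile(tone, (len(CHANNEL_NAMES), 1)),
        channel_labels=list(CHANNEL_NAMES),
        fs=fs,
        kss_timeline=[(0.0, kss)],
        subject_id="tone",
        state=None,
    )
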