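"""Burg autoregressive spectral estimation and band-power features.

An epoch of EEG is modelled per channel as an autoregressive (AR) process

    x(n) = -sum_{k=1..p} a_k x(n-k) + u(n),   u ~ white noise, var sigma^2,

whose coefficients are estimated with the Burg lattice recursion (joint
minimisation of forward and backward prediction-error power).  The parametric
power spectral density

    P(f) = sigma_p^2 / |1 + sum_k a_k exp(-2*pi*i*f*k/fs)|^2

is evaluated on a fixed frequency grid, integrated over the canonical EEG
bands (delta/theta/alpha/beta) with a rectangle rule, and normalised by the
total-band power to give the relative PSD (RPSD) — a scale-invariant feature
robust to inter-subject amplitude differences.

The shipped AR order default is p = 10; :func:`select_order_aic` offers
Akaike-criterion order selection as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InputError

__all__ = [
    "ARModel",
    "BandDefinition",
    "BandSpectralFeatures",
    "DEFAULT_BANDS",
    "TOTAL_BAND",
    "DEFAULT_ORDER",
    "GRID_STEP",
    "fit_burg",
    "select_order_aic",
    "burg_psd",
    "band_power",
    "rpsd",
    "extract_features",
]

#: Canonical EEG analysis bands, half-open [low, high) in Hz.  The nominal
#: delta band starts at 0 Hz; after the 1 Hz high-pass of preprocessing its
#: effective lower edge is 1 Hz.
DEFAULT_BANDS = (
    ("delta", 0.0, 4.0),
    ("theta", 4.0, 7.0),
    ("alpha", 8.0, 13.0),
    ("beta", 14.0, 30.0),
)

#: Denominator band for RPSD: the continuous span of the four analysis bands.
#: The 7-8 Hz theta-alpha gap is included (the normalising integral runs
#: continuously from the lowest to the highest analysis frequency).
TOTAL_BAND = ("total", 1.0, 30.0)

DEFAULT_ORDER = 10
GRID_STEP = 0.25  # Hz


@dataclass(frozen=True)
class BandDefinition:
    """A half-open frequency interval [f_low, f_high) in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not (0 <= self.f_low < self.f_high):
            raise InputError(
                f"band {self.name!r}: need 0 <= f_low < f_high, "
                f"got [{self.f_low}, {self.f_high})"
            )


def _as_band(band) -> BandDefinition:
    if isinstance(band, BandDefinition):
        return band
    return BandDefinition(*band)


@dataclass
class ARModel:
    """Autoregressive model fitted to one channel.

    ``coefficients`` are a_1..a_p in the convention where the PSD denominator
    is ``|1 + sum a_k z^-k|^2``; ``final_error`` is the final prediction-error
    power of the Burg recursion, which doubles as the innovation-variance
    estimate ``noise_variance``.
    """

    coefficients: np.ndarray
    order: int
    noise_variance: float
    final_error: float

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.order != self.coefficients.size or self.order < 1:
            raise InputError("order must equal len(coefficients) >= 1")
        if self.noise_variance < 0 or self.final_error < 0:
            raise InputError("error powers must be non-negative")


@dataclass
class BandSpectralFeatures:
    """Per-channel, per-band absolute and relative band power for one epoch.

    ``psd`` and ``rpsd`` are DataFrames indexed by channel name with one
    column per band; ``grid`` is the frequency axis the PSDs were evaluated
    on.
    """

    psd: pd.DataFrame
    rpsd: pd.DataFrame
    grid: np.ndarray
    bands: tuple = DEFAULT_BANDS
    total: tuple = TOTAL_BAND
    order: int = DEFAULT_ORDER
    state: str | None = None
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Burg recursion
# ---------------------------------------------------------------------------

def _burg_multi(x: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Burg recursion vectorised over rows of ``x`` (channels, samples).

    Returns (coefficients (C, p), final prediction-error power (C,)).
    """
    x = np.asarray(x, dtype=float)
    c, n = x.shape
    a = np.zeros((c, 0))
    ef = x.copy()
    eb = x.copy()
    err = np.einsum("ij,ij->i", x, x) / n
    for _ in range(p):
        efp = ef[:, 1:]
        ebp = eb[:, :-1]
        num = -2.0 * np.einsum("ij,ij->i", ebp, efp)
        den = np.einsum("ij,ij->i", efp, efp) + np.einsum("ij,ij->i", ebp, ebp)
        if np.any(den <= 0):
            raise DegenerateInputError(
                "prediction-error power vanished; signal is (locally) constant"
            )
        k = num / den
        ef = efp + k[:, None] * ebp
        eb = ebp + k[:, None] * efp
        a = np.concatenate([a + k[:, None] * a[:, ::-1], k[:, None]], axis=1)
        err = (1.0 - k * k) * err
    return a, err


def fit_burg(signal: np.ndarray, p: int = DEFAULT_ORDER) -> ARModel:
    """Fit an AR(p) model to a single channel by the Burg method.

    Parameters
    ----------
    signal : 1-D array of samples.
    p : AR order, ``1 <= p < len(signal)``.
    """
    x = np.asarray(signal, dtype=float).ravel()
    if p < 1:
        raise InputError(f"AR order must be >= 1, got {p}")
    if p >= x.size:
        raise InputError(f"AR order {p} >= signal length {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant signal has no AR structure")
    a, err = _burg_multi(x[None, :], p)
    e = float(err[0])
    return ARModel(coefficients=a[0], order=p, noise_variance=e, final_error=e)


def select_order_aic(signal: np.ndarray, p_max: int) -> int:
    """Choose the AR order minimising AIC = n*ln(e_p) + 2p over 1..p_max.

    Ties break toward the smaller order.
    """
    x = np.asarray(signal, dtype=float).ravel()
    if p_max < 1:
        raise InputError("p_max must be >= 1")
    n = x.size
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant signal has no AR structure")
    if p_max >= n:
        raise InputError(f"p_max {p_max} >= signal length {n}")
    # one pass of the recursion yields every intermediate-order error power
    best_p, best_aic = 1, np.inf
    ef = x.copy()
    eb = x.copy()
    err = float(np.dot(x, x)) / n
    for m in range(1, p_max + 1):
        efp, ebp = ef[1:], eb[:-1]
        den = np.dot(efp, efp) + np.dot(ebp, ebp)
        if den <= 0:
            raise DegenerateInputError("prediction-error power vanished")
        k = -2.0 * np.dot(ebp, efp) / den
        ef = efp + k * ebp
        eb = ebp + k * efp
        err *= 1.0 - k * k
        aic = n * np.log(err) + 2 * m
        if aic < best_aic:
            best_aic, best_p = aic, m
    return best_p


# ---------------------------------------------------------------------------
# Spectrum and band powers
# ---------------------------------------------------------------------------

def burg_psd(model: ARModel, freqs: np.ndarray, fs: float) -> np.ndarray:
    """Evaluate the one-sided AR spectrum on ``freqs`` (Hz).

    Scaled as a one-sided density (2/fs factor) so that the rectangle-rule
    integral over [0, fs/2] approximates the signal variance.
    """
    f = np.asarray(freqs, dtype=float)
    if np.any(f < 0) or np.any(f > fs / 2):
        raise InputError("frequencies must lie in [0, fs/2]")
    k = np.arange(1, model.order + 1)
    a = np.exp(-2j * np.pi * np.outer(f / fs, k)) @ model.coefficients
    denom = np.abs(1.0 + a) ** 2
    return (2.0 / fs) * model.final_error / denom


def _psd_multi(coef: np.ndarray, err: np.ndarray, freqs: np.ndarray,
               fs: float) -> np.ndarray:
    """AR spectra for many channels at once: coef (C, p) -> (C, F)."""
    p = coef.shape[1]
    k = np.arange(1, p + 1)
    e = np.exp(-2j * np.pi * np.outer(freqs / fs, k))  # (F, p)
    denom = np.abs(1.0 + coef @ e.T) ** 2  # (C, F)
    return (2.0 / fs) * err[:, None] / denom


def band_power(psd: np.ndarray, grid: np.ndarray, band) -> float:
    """Rectangle-rule power in the half-open band [f_low, f_high)."""
    band = _as_band(band)
    grid = np.asarray(grid, dtype=float)
    psd = np.asarray(psd, dtype=float)
    mask = (grid >= band.f_low) & (grid < band.f_high)
    if not mask.any():
        raise InputError(f"band {band.name!r} contains no grid points")
    step = float(grid[1] - grid[0]) if grid.size > 1 else 1.0
    return float(psd[..., mask].sum(axis=-1) * step) if psd.ndim == 1 else (
        psd[..., mask].sum(axis=-1) * step
    )


def rpsd(psd: np.ndarray, grid: np.ndarray, band, total=TOTAL_BAND) -> float:
    """Relative PSD: band power divided by total-band power, in [0, 1]."""
    band = _as_band(band)
    total = _as_band(total)
    if not (band.f_low >= total.f_low and band.f_high <= total.f_high):
        raise InputError(
            f"band {band.name!r} not contained in total band {total.name!r}"
        )
    denom = band_power(psd, grid, total)
    if np.ndim(denom) == 0 and denom == 0:
        raise DegenerateInputError("zero total power")
    return band_power(psd, grid, band) / denom


def default_grid(fs: float, step: float = GRID_STEP) -> np.ndarray:
    """Uniform frequency grid 0..fs/2 inclusive."""
    return np.arange(0.0, fs / 2 + step / 2, step)


def extract_features(epoch, bands=DEFAULT_BANDS, order: int = DEFAULT_ORDER,
                     total=TOTAL_BAND, grid_step: float = GRID_STEP
                     ) -> BandSpectralFeatures:
    """Per-channel Burg PSD and RPSD tables for one epoch.

    ``epoch`` needs ``samples`` (channels x time), ``fs`` and
    ``channel_labels`` attributes (see :class:`eegfatigue.preprocess.Epoch`).
    """
    x = np.asarray(epoch.samples, dtype=float)
    if x.ndim != 2:
        raise InputError("epoch samples must be channels x time")
    fs = float(epoch.fs)
    labels = list(epoch.channel_labels)
    bands = tuple(_as_band(b) for b in bands)
    total = _as_band(total)
    grid = default_grid(fs, grid_step)

    coef, err = _burg_multi(x, order)
    psd = _psd_multi(coef, err, grid, fs)

    step = grid[1] - grid[0]
    total_mask = (grid >= total.f_low) & (grid < total.f_high)
    total_power = psd[:, total_mask].sum(axis=1) * step
    if np.any(total_power == 0):
        raise DegenerateInputError("zero total power in at least one channel")

    bp = {}
    rp = {}
    for b in bands:
        mask = (grid >= b.f_low) & (grid < b.f_high)
        if not mask.any():
            raise InputError(f"band {b.name!r} contains no grid points")
        bp[b.name] = psd[:, mask].sum(axis=1) * step
        # RPSD numerator is clipped to the total band, so e.g. the nominal
        # 0 Hz delta edge becomes the 1 Hz edge of the analysis span and
        # every ratio stays in [0, 1]
        cmask = mask & total_mask
        rp[b.name] = psd[:, cmask].sum(axis=1) * step / total_power

    return BandSpectralFeatures(
        psd=pd.DataFrame(bp, index=labels),
        rpsd=pd.DataFrame(rp, index=labels),
        grid=grid,
        bands=bands,
        total=total,
        order=order,
        state=getattr(epoch, "state", None),
    )


def write_features(features: BandSpectralFeatures, path) -> None:
    """Write the feature tables as TSV plus a JSON sidecar with metadata."""
    import json
    from pathlib import Path

    path = Path(path)
    table = pd.concat(
        {"psd": features.psd, "rpsd": features.rpsd}, axis=1
    )
    table.columns = [f"{band}_{kind}" for kind, band in table.columns]
    table.to_csv(path.with_suffix(".tsv"), sep="\t", index_label="channel")
    meta = {
        "grid_start": float(features.grid[0]),
        "grid_stop": float(features.grid[-1]),
        "grid_step": float(features.grid[1] - features.grid[0]),
        "bands": [[b.name, b.f_low, b.f_high] for b in map(_as_band, features.bands)],
        "total": list(_as_band(features.total).__dict__.values()),
        "order": features.order,
        "state": features.state,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
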