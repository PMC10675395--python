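"""Reading and writing recordings.

Two on-disk forms are supported:

* EDF (European Data Format), read through mne's bundled EDF reader;
* a plain-text matrix — one header line of tab-separated channel labels,
  then one row per sample — with a JSON sidecar (same stem, ``.json``)
  carrying the sampling rate, the KSS timeline and, for simulated data, the
  true state label.  The simulator writes this text form.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np

from .errors import InputError
from .preprocess import RawRecording
from .topomap import CHANNEL_NAMES

__all__ = ["read_recording", "read_edf", "read_text_matrix",
           "write_text_recording", "check_channels"]


def check_channels(labels, expected=CHANNEL_NAMES) -> None:
    """Raise InputError naming any missing or unexpected channels."""
    missing = [c for c in expected if c not in labels]
    extra = [c for c in labels if c not in expected]
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"missing channel(s): {', '.join(missing)}")
        if extra:
            parts.append(f"unexpected channel(s): {', '.join(extra)}")
        raise InputError("; ".join(parts))


def _sidecar(path: Path) -> dict:
    side = path.with_suffix(".json")
    if side.exists():
        return json.loads(side.read_text())
    return {}


def read_edf(path, verify_channels: bool = True) -> RawRecording:
    """Read a 32-channel EDF file (KSS timeline from the JSON sidecar)."""
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise InputError(f"empty or missing EDF file: {path}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import mne
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = list(raw.ch_names)
    if verify_channels:
        check_channels(labels)
    meta = _sidecar(path)
    return RawRecording(
        samples=raw.get_data() * 1e6,  # volts -> microvolts
        channel_labels=labels,
        fs=float(raw.info["sfreq"]),
        kss_timeline=[tuple(x) for x in meta.get("kss_timeline", [])],
        subject_id=meta.get("subject_id", path.stem),
        state=meta.get("state"),
    )


def read_text_matrix(path, fs: float | None = None,
                     verify_channels: bool = True) -> RawRecording:
    """Read the delimiter-separated matrix form (header = channel labels)."""
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise InputError(f"empty or missing file: {path}")
    with open(path) as fh:
        header = fh.readline().strip()
    if not header:
        raise InputError(f"no channel header line in {path}")
    labels = header.replace(",", "\t").split("\t")
    labels = [c.strip() for c in labels if c.strip()]
    if verify_channels:
        check_channels(labels)
    data = np.loadtxt(path, skiprows=1,
                      delimiter="," if "," in header else None)
    if data.ndim != 2 or data.shape[1] != len(labels):
        raise InputError(
            f"matrix in {path} has {data.shape} entries for "
            f"{len(labels)} channels"
        )
    meta = _sidecar(path)
    fs = fs or meta.get("fs")
    if fs is None:
        raise InputError(f"no sampling rate for {path} (sidecar or argument)")
    return RawRecording(
        samples=data.T,
        channel_labels=labels,
        fs=float(fs),
        kss_timeline=[tuple(x) for x in meta.get("kss_timeline", [])],
        subject_id=meta.get("subject_id", path.stem),
        state=meta.get("state"),
    )


def read_recording(path, **kwargs) -> RawRecording:
    """Dispatch on extension: .edf -> EDF reader, else text matrix."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_edf(path, **kwargs)
    return read_text_matrix(path, **kwargs)


def write_text_recording(recording: RawRecording, path) -> Path:
    """Write the text-matrix form plus its JSON sidecar; returns the path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = "\t".join(recording.channel_labels)
    np.savetxt(path, recording.samples.T, fmt="%.4f", delimiter="\t",
               header=header, comments="")
    sidecar = {
        "fs": recording.fs,
        "kss_timeline": [[float(t), int(k)]
                         for t, k in recording.kss_timeline],
        "subject_id": recording.subject_id,
        "state": recording.state,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path
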