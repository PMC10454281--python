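"""Raw recording I/O (BDF/EDF), trigger extraction, and the epoch container.

Raw Biosemi files are read through MNE; trigger events are extracted from the
status channel by rising-edge detection.  Epoch containers are HDF5 files with
a format version and a SHA-256 checksum for lossless round-trips.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .epochs import EpochedEEG

CONTAINER_VERSION = 1


class RawFormatError(ValueError):
    pass


class NoEventsError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


class ContainerError(ValueError):
    pass


@dataclass
class RawRecording:
    """Continuous multichannel recording in microvolts with trigger events."""

    data: np.ndarray  # channels x samples, microvolts
    sfreq: float
    events: list  # (sample_index, event_code) pairs
    ch_names: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("raw data contains non-finite samples")
        n = self.data.shape[1]
        self.events = [(int(s), int(c)) for s, c in self.events]
        for s, _ in self.events:
            if not (0 <= s < n):
                raise ValueError("event sample index outside record")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def extract_trigger_events(trigger: np.ndarray) -> list:
    """Rising-edge events from a trigger/status channel.

    An event is emitted wherever the (integer-rounded) trigger value steps
    from a lower to a higher value; the event code is the new value.
    """
    trig = np.round(np.asarray(trigger, dtype=np.float64)).astype(np.int64)
    trig = trig - trig.min() if trig.size and trig.min() < 0 else trig
    edges = np.flatnonzero(np.diff(trig) > 0) + 1
    return [(int(s), int(trig[s])) for s in edges]


def read_raw_recording(path, fmt: str | None = None, layout=None,
                       stim_channel: str | None = None) -> RawRecording:
    """Read a BDF or EDF file into a :class:`RawRecording` (microvolts).

    The trigger channel is located by name (``stim_channel``, or any channel
    whose name contains 'status' or 'trig'); events are its rising edges.
    Raises :class:`NoEventsError` when no trigger channel or no trigger pulse
    is present, and :class:`ConfigurationError` when a supplied layout does not
    match the recording's channel count.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise RawFormatError(f"no such file: {path}")
    if fmt is None:
        fmt = path.suffix.lstrip(".").upper()
    fmt = fmt.upper()
    try:
        if fmt == "BDF":
            raw = mne.io.read_raw_bdf(path, preload=True, verbose="error")
        elif fmt == "EDF":
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        else:
            raise RawFormatError(f"unsupported format {fmt!r} (expected BDF or EDF)")
    except RawFormatError:
        raise
    except Exception as exc:
        raise RawFormatError(f"could not parse {path} as {fmt}: {exc}") from exc

    names = list(raw.ch_names)
    if stim_channel is not None:
        trig_candidates = [n for n in names if n == stim_channel]
    else:
        trig_candidates = [n for n in names if "status" in n.lower() or "trig" in n.lower()]
    if not trig_candidates:
        raise NoEventsError("no trigger/status channel found in recording")
    trig_name = trig_candidates[0]

    data = raw.get_data()  # volts for EEG channels
    trig_idx = names.index(trig_name)
    trig_vals = data[trig_idx].copy()
    if trig_vals.size and np.max(np.abs(trig_vals)) < 0.1:
        trig_vals *= 1e6  # undo volt scaling applied to a uV-typed status channel
    events = extract_trigger_events(trig_vals)
    if not events:
        raise NoEventsError("trigger channel present but contains no events")

    eeg_idx = [i for i in range(len(names)) if i != trig_idx]
    eeg = data[eeg_idx] * 1e6  # -> microvolts
    ch_names = [names[i] for i in eeg_idx]
    if layout is not None and layout.n_channels != len(ch_names):
        raise ConfigurationError(
            f"layout has {layout.n_channels} channels, recording has {len(ch_names)}")
    return RawRecording(data=eeg, sfreq=float(raw.info["sfreq"]), events=events, ch_names=ch_names)


def _checksum(data: np.ndarray, times: np.ndarray, ch_names: list[str]) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(data).tobytes())
    h.update(np.ascontiguousarray(times).tobytes())
    h.update(json.dumps(list(ch_names)).encode())
    return h.hexdigest()


def save_epochs(ep: EpochedEEG, path) -> None:
    """Persist an :class:`EpochedEEG` losslessly to a versioned HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "eegmotor-epochs"
        f.attrs["version"] = CONTAINER_VERSION
        f.attrs["sfreq"] = ep.sfreq
        f.attrs["is_csd"] = bool(ep.is_csd)
        f.create_dataset("data", data=ep.data)
        f.create_dataset("times", data=ep.times)
        f.create_dataset("ch_names", data=np.array(ep.ch_names, dtype=h5py.string_dtype()))
        if ep.metadata is not None:
            f.attrs["metadata_json"] = ep.metadata.to_json(orient="split")
        f.attrs["checksum"] = _checksum(ep.data, ep.times, ep.ch_names)


def load_epochs(path) -> EpochedEEG:
    """Load a container written by :func:`save_epochs`, verifying the checksum."""
    try:
        f = h5py.File(path, "r")
    except Exception as exc:
        raise ContainerError(f"cannot open epoch container {path}: {exc}") from exc
    with f:
        if f.attrs.get("format") != "eegmotor-epochs":
            raise ContainerError("not an eegmotor epoch container")
        version = int(f.attrs.get("version", -1))
        if version != CONTAINER_VERSION:
            raise ContainerError(f"container version {version} != {CONTAINER_VERSION}")
        data = f["data"][()]
        times = f["times"][()]
        ch_names = [s.decode() if isinstance(s, bytes) else str(s) for s in f["ch_names"][()]]
        if _checksum(data, times, ch_names) != f.attrs.get("checksum"):
            raise ContainerError("checksum mismatch: container corrupted or truncated")
        meta = None
        if "metadata_json" in f.attrs:
            meta = pd.read_json(io_wrap(f.attrs["metadata_json"]), orient="split")
        return EpochedEEG(data=data, sfreq=float(f.attrs["sfreq"]), times=times,
                          ch_names=ch_names, metadata=meta, is_csd=bool(f.attrs["is_csd"]))


def io_wrap(text: str):
    import io

    return io.StringIO(text)
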