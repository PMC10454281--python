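"""Minimal 16-bit EDF writer for test fixtures (synthetic recordings only).

Writes just enough of the EDF header and record structure for readers to
recover channel names, sampling rate, physical values and a status/trigger
channel.  Not a general-purpose exporter.
"""

from __future__ import annotations

import numpy as np


def _field(text: str, width: int) -> bytes:
    s = str(text)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path, signals: dict, sfreq: int, phys_range: float = 1000.0) -> None:
    """Write named signals (label -> 1-D array) to an EDF file.

    EEG-like channels are scaled into ``+-phys_range`` microvolts; a channel
    named 'Status' is written with a unit digital-physical mapping so integer
    trigger codes survive the round trip.  All signals must share one length,
    which must be a multiple of ``sfreq`` (1-second records).
    """
    labels = list(signals)
    arrs = [np.asarray(signals[l], dtype=np.float64) for l in labels]
    n = arrs[0].size
    if any(a.size != n for a in arrs) or n % sfreq:
        raise ValueError("signals must share a length that is a multiple of sfreq")
    n_records = n // sfreq
    ns = len(labels)

    header = b"".join([
        _field("0", 8),
        _field("synthetic test subject", 80),
        _field("synthetic test recording", 80),
        _field("01.01.24", 8),
        _field("00.00.00", 8),
        _field(str(256 * (ns + 1)), 8),
        _field("", 44),
        _field(str(n_records), 8),
        _field("1", 8),
        _field(str(ns), 4),
    ])

    dig_min, dig_max = -32768, 32767
    phys = []
    for label, a in zip(labels, arrs):
        if label.lower() == "status":
            phys.append((float(dig_min), float(dig_max)))
        else:
            phys.append((-phys_range, phys_range))

    per_signal = b"".join([
        b"".join(_field(l, 16) for l in labels),
        b"".join(_field("synthetic", 80) for _ in labels),
        b"".join(_field("uV", 8) for _ in labels),
        b"".join(_field(f"{p[0]:g}", 8) for p in phys),
        b"".join(_field(f"{p[1]:g}", 8) for p in phys),
        b"".join(_field(str(dig_min), 8) for _ in labels),
        b"".join(_field(str(dig_max), 8) for _ in labels),
        b"".join(_field("", 80) for _ in labels),
        b"".join(_field(str(sfreq), 8) for _ in labels),
        b"".join(_field("", 32) for _ in labels),
    ])

    digitized = []
    for (pmin, pmax), a in zip(phys, arrs):
        scale = (dig_max - dig_min) / (pmax - pmin)
        d = np.round((np.clip(a, pmin, pmax) - pmin) * scale + dig_min)
        digitized.append(d.astype("<i2"))

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        for r in range(n_records):
            for d in digitized:
                fh.write(d[r * sfreq:(r + 1) * sfreq].tobytes())
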