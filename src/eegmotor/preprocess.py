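"""Continuous-signal preprocessing: zero-phase filters, epoching, resampling,
and spherical-spline interpolation of bad channels.

Filter defaults follow the reference recording pipeline: 0.5-70 Hz 4th-order
Butterworth band limits and a 50 Hz notch (Q = 45), all applied forward and
backward (zero phase, squared magnitude response).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal

from .epochs import EpochedEEG, window_to_sample_bounds
from .layout import ElectrodeLayout
from .rawio import RawRecording

logger = logging.getLogger(__name__)


class NoEpochsError(ValueError):
    pass


def bandpass_zero_phase(rec: RawRecording, low: float = 0.5, high: float = 70.0,
                        order: int = 4) -> RawRecording:
    """Cascaded high-pass + low-pass Butterworth, applied with filtfilt.

    Forward-backward application doubles the effective order and cancels the
    phase delay exactly.
    """
    nyq = rec.sfreq / 2.0
    if not (0 < low < high):
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(f"low-pass corner {high} Hz must be below Nyquist ({nyq} Hz)")
    b_hp, a_hp = signal.butter(order, low / nyq, btype="highpass")
    b_lp, a_lp = signal.butter(order, high / nyq, btype="lowpass")
    out = signal.filtfilt(b_hp, a_hp, rec.data, axis=-1)
    out = signal.filtfilt(b_lp, a_lp, out, axis=-1)
    return RawRecording(data=out, sfreq=rec.sfreq, events=list(rec.events), ch_names=list(rec.ch_names))


def notch_filter(rec: RawRecording, center: float = 50.0, q: float = 45.0) -> RawRecording:
    """Zero-phase second-order IIR notch (default 50 Hz, Q = 45)."""
    nyq = rec.sfreq / 2.0
    if not (0 < center < nyq):
        raise ValueError("notch frequency must lie below Nyquist")
    if q <= 0:
        raise ValueError("quality factor must be positive")
    b, a = signal.iirnotch(center, q, fs=rec.sfreq)
    out = signal.filtfilt(b, a, rec.data, axis=-1)
    return RawRecording(data=out, sfreq=rec.sfreq, events=list(rec.events), ch_names=list(rec.ch_names))


def extract_epochs(rec: RawRecording, window_ms: tuple[float, float] = (-4500.0, 2500.0),
                   events: list | None = None, metadata_base: dict | None = None) -> EpochedEEG:
    """Cut response-locked epochs around each event (half-open sample window).

    Events whose window does not fit inside the record are dropped (logged).
    """
    start, end = window_ms
    if not (start < 0 < end):
        raise ValueError("epoch window must bracket 0 ms")
    events = rec.events if events is None else events
    i0, i1 = window_to_sample_bounds(window_ms, rec.sfreq)
    trials, kept_events, dropped = [], [], 0
    for samp, code in events:
        lo, hi = samp + i0, samp + i1
        if lo < 0 or hi > rec.n_samples:
            dropped += 1
            continue
        trials.append(rec.data[:, lo:hi])
        kept_events.append((samp, code))
    if dropped:
        logger.info("extract_epochs: dropped %d events with incomplete windows", dropped)
    if not trials:
        raise NoEpochsError("no event allows a complete epoch window")
    times = (i0 + np.arange(i1 - i0)) / rec.sfreq * 1000.0
    meta = None
    if metadata_base is not None or kept_events:
        import pandas as pd

        meta = pd.DataFrame({
            "event_sample": [s for s, _ in kept_events],
            "event_code": [c for _, c in kept_events],
        })
        for k, v in (metadata_base or {}).items():
            meta[k] = v
    return EpochedEEG(data=np.stack(trials), sfreq=rec.sfreq, times=times,
                      ch_names=list(rec.ch_names), metadata=meta)


def resample_epochs(ep: EpochedEEG, target_rate: float) -> EpochedEEG:
    """Polyphase resampling (anti-aliased) to ``target_rate``; 0 ms stays on-grid."""
    if target_rate <= 0:
        raise ValueError("target rate must be positive")
    if target_rate == ep.sfreq:
        return ep.copy_with()
    if target_rate > ep.sfreq:
        raise ValueError("only downsampling is supported")
    from fractions import Fraction

    frac = Fraction(target_rate / ep.sfreq).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    data = signal.resample_poly(ep.data, up, down, axis=-1)
    n_new = data.shape[-1]
    offset = int(round(ep.times[0] * target_rate / 1000.0))
    times = (offset + np.arange(n_new)) / target_rate * 1000.0
    return ep.copy_with(data=data, sfreq=float(target_rate), times=times)


def interpolate_bad_channels(ep: EpochedEEG, bad, layout: ElectrodeLayout,
                             m: int = 4, lam: float = 1e-5, max_degree: int = 10) -> EpochedEEG:
    """Replace bad-channel series with the spherical-spline interpolant fitted
    on the good channels, per sample.

    ``bad`` may be channel labels or indices; an empty set is the identity
    (with a warning).
    """
    from .csd import interpolation_matrix

    if list(layout.labels) != list(ep.ch_names):
        raise ValueError("layout and epochs have different channel sets")
    bad_idx = sorted({b if isinstance(b, (int, np.integer)) else ep.ch_names.index(b) for b in bad})
    if not bad_idx:
        logger.warning("interpolate_bad_channels: empty bad set, returning input unchanged")
        return ep.copy_with()
    good_idx = [i for i in range(ep.n_channels) if i not in bad_idx]
    if len(good_idx) < 4:
        raise ValueError("need at least 4 good channels for spherical-spline interpolation")
    M = interpolation_matrix(layout, good_idx, bad_idx, m=m, lam=lam, max_degree=max_degree)
    data = ep.data.copy()
    data[:, bad_idx, :] = np.einsum("bg,kgt->kbt", M, ep.data[:, good_idx, :])
    return ep.copy_with(data=data)
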