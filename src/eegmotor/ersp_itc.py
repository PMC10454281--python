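"""Single-trial-gain ERSP and inter-trial coherence (ITC).

ERSP follows the single-trial gain model: each trial's power is divided by
that trial's own mean baseline power before averaging,

    P_k%(f,t)   = |F_k(f,t)|^2 / mu'_B(f,k)
    ERSP(f,t)   = 10 * log10( (1/n) * sum_k P_k%(f,t) )   [dB]

with the baseline window [-3500, -3000) ms by default.  ITC is the magnitude
of the across-trial average of unit phase vectors,

    ITC(c,f,t) = | (1/n) * sum_k exp(i * phi_k(c,f,t)) |,

0 for random phases, 1 for identical phases across trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .epochs import window_to_sample_bounds
from .timefreq import FrequencyGrid, TFDecomposition

logger = logging.getLogger(__name__)

DEFAULT_BASELINE_MS = (-3500.0, -3000.0)


@dataclass
class ChannelFreqTimeMap:
    """Real-valued channels x frequencies x samples map (ERSP in dB, or ITC)."""

    values: np.ndarray
    kind: str  # "ERSP_dB" | "ITC"
    grid: FrequencyGrid
    times: np.ndarray
    sfreq: float
    ch_names: list[str]
    n_trials: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 3:
            raise ValueError("map must be channels x frequencies x samples")
        if self.kind == "ITC":
            finite = v[np.isfinite(v)]
            if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
                raise ValueError("ITC values must lie in [0, 1]")
        self.values = v

    def time_mask(self, window_ms: tuple[float, float]) -> np.ndarray:
        i0, i1 = window_to_sample_bounds(window_ms, self.sfreq)
        k = np.round(self.times * self.sfreq / 1000.0).astype(int)
        return (k >= i0) & (k < i1)


def baseline_mean_power(tf: TFDecomposition,
                        window_ms: tuple[float, float] = DEFAULT_BASELINE_MS) -> np.ndarray:
    """Per-trial mean baseline power mu'_B: (trials, channels, freqs)."""
    mask = tf.time_mask(window_ms)
    m = int(mask.sum())
    if m < 1:
        raise ValueError("baseline window contains no samples")
    return (np.abs(tf.coeffs[..., mask]) ** 2).mean(axis=-1)


def single_trial_gain(tf: TFDecomposition, base: np.ndarray) -> np.ndarray:
    """P_k% = |F_k|^2 / mu'_B(f,k); cells with zero baseline become NaN.

    NaN cells are excluded from the across-trial mean in :func:`ersp` (with a
    logged count); they can only arise for exactly zero signals.
    """
    power = np.abs(tf.coeffs) ** 2
    base = np.asarray(base, dtype=np.float64)
    if base.shape != power.shape[:3]:
        raise ValueError("baseline must be (trials, channels, freqs)")
    with np.errstate(divide="ignore", invalid="ignore"):
        gains = power / base[..., None]
    bad = ~np.isfinite(gains)
    if bad.any():
        logger.info("single_trial_gain: %d cells with zero baseline flagged missing", int(bad.sum()))
        gains[bad] = np.nan
    return gains


def ersp(gains: np.ndarray, grid: FrequencyGrid | None = None, times=None,
         sfreq: float | None = None, ch_names=None) -> ChannelFreqTimeMap | np.ndarray:
    """10*log10 of the across-trial mean single-trial gain.

    With only ``gains`` supplied, returns the raw (channels, freqs, samples)
    dB array; with grid/times/sfreq/ch_names it is wrapped in a
    :class:`ChannelFreqTimeMap`.
    """
    g = np.asarray(gains, dtype=np.float64)
    if g.shape[0] < 1:
        raise ValueError("need at least one trial")
    with np.errstate(invalid="ignore"):
        mean_gain = np.nanmean(g, axis=0)
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(mean_gain)
    if grid is None:
        return db
    return ChannelFreqTimeMap(values=db, kind="ERSP_dB", grid=grid, times=np.asarray(times),
                              sfreq=float(sfreq), ch_names=list(ch_names), n_trials=g.shape[0])


def resultant_length(phases: np.ndarray, axis: int = 0) -> np.ndarray:
    """Circular resultant length R = |mean(exp(i*phi))| along ``axis``."""
    return np.abs(np.exp(1j * np.asarray(phases)).mean(axis=axis))


def itc(tf: TFDecomposition) -> ChannelFreqTimeMap:
    """Inter-trial coherence map from a TF decomposition (needs >= 2 trials)."""
    if tf.n_trials < 2:
        raise ValueError("ITC requires at least 2 trials")
    values = np.clip(resultant_length(tf.phase(), axis=0), 0.0, 1.0)
    return ChannelFreqTimeMap(values=values, kind="ITC", grid=tf.grid, times=tf.times.copy(),
                              sfreq=tf.sfreq, ch_names=list(tf.ch_names), n_trials=tf.n_trials)


def band_window_average(m: ChannelFreqTimeMap, band: str,
                        window_ms: tuple[float, float]) -> tuple[np.ndarray, int]:
    """Mean over band frequencies [low, high) and window samples [start, end).

    Returns (per-channel vector, number of (f,t) cells averaged).
    """
    fidx = m.grid.band_indices(band)
    tmask = m.time_mask(window_ms)
    if not tmask.any():
        raise ValueError("window contains no samples")
    sub = m.values[:, fidx][:, :, tmask]
    n_cells = fidx.size * int(tmask.sum())
    return np.nanmean(sub, axis=(1, 2)), n_cells
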