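"""Complex Morlet continuous wavelet transform on a logarithmic frequency grid.

The mother wavelet is the analytic complex Morlet

    psi(t) = (pi * B)^(-1/2) * exp(-t^2 / B) * exp(i * 2*pi*C * t)

with bandwidth parameter B (s^2) and centre frequency C (Hz), the 'cmor1-1'
wavelet for B = C = 1.  For a target frequency f the wavelet is dilated by
a = C / f; kernels are L1-normalized and doubled so that the coefficient
magnitude for a unit-amplitude in-band sinusoid is ~1 and its argument is the
instantaneous phase of the cosine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import fft, ifft, next_fast_len

from .epochs import EpochedEEG, window_to_sample_bounds

#: canonical EEG band edges in Hz; membership is half-open [low, high)
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 15.0),
    "beta": (15.0, 30.0),
    "gamma": (30.0, 70.0),
}


@dataclass
class FrequencyGrid:
    """Geometric frequency grid f_k = fmin * ratio^k."""

    freqs: np.ndarray
    ratio: float
    bands: dict = field(default_factory=lambda: dict(BANDS))

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=np.float64)
        if f.size == 0 or np.any(np.diff(f) <= 0):
            raise ValueError("frequency grid must be non-empty and strictly increasing")
        if f.size > 1:
            r = f[1:] / f[:-1]
            if not np.allclose(r, self.ratio, rtol=0, atol=1e-9):
                raise ValueError("grid spacing does not match the stated ratio")
        self.freqs = f

    @property
    def n_freqs(self) -> int:
        return self.freqs.size

    def band_mask(self, band: str) -> np.ndarray:
        """Half-open membership mask [low, high) for a named band."""
        if band not in self.bands:
            raise KeyError(f"unknown band {band!r}")
        lo, hi = self.bands[band]
        return (self.freqs >= lo) & (self.freqs < hi)

    def band_indices(self, band: str) -> np.ndarray:
        idx = np.flatnonzero(self.band_mask(band))
        if idx.size == 0:
            raise ValueError(f"band {band!r} has no grid frequencies")
        return idx


def make_frequency_grid(fmin: float = 0.32, fmax: float = 73.0,
                        ratio: float = 1.1) -> FrequencyGrid:
    """Ascending grid fmin * ratio^k for k = 0..floor(log(fmax/fmin)/log(ratio))."""
    if not (0 < fmin < fmax):
        raise ValueError("need 0 < fmin < fmax")
    if ratio <= 1:
        raise ValueError("ratio must exceed 1")
    k_max = int(np.floor(np.round(np.log(fmax / fmin) / np.log(ratio), 9)))
    freqs = fmin * ratio ** np.arange(k_max + 1)
    return FrequencyGrid(freqs=freqs, ratio=ratio)


@dataclass
class TFDecomposition:
    """Complex Morlet coefficients: trials x channels x frequencies x samples."""

    coeffs: np.ndarray
    grid: FrequencyGrid
    times: np.ndarray  # ms, from the source epochs
    sfreq: float
    ch_names: list[str]
    bandwidth: float = 1.0
    center_freq: float = 1.0
    edge_mask: np.ndarray | None = None  # (freqs, samples) True where edge-contaminated

    @property
    def n_trials(self) -> int:
        return self.coeffs.shape[0]

    def power(self) -> np.ndarray:
        """|F|^2 per trial, channel, frequency and sample."""
        return np.abs(self.coeffs) ** 2

    def phase(self) -> np.ndarray:
        """arg F in (-pi, pi]."""
        return np.angle(self.coeffs)

    def time_mask(self, window_ms: tuple[float, float]) -> np.ndarray:
        i0, i1 = window_to_sample_bounds(window_ms, self.sfreq)
        k = np.round(self.times * self.sfreq / 1000.0).astype(int)
        return (k >= i0) & (k < i1)


def morlet_kernel(freq: float, sfreq: float, bandwidth: float = 1.0,
                  center_freq: float = 1.0, truncate_sigmas: float = 5.0) -> np.ndarray:
    """Sampled, L1-normalized analytic Morlet kernel dilated to ``freq``."""
    a = center_freq / freq  # dilation in seconds
    sigma_t = a * np.sqrt(bandwidth / 2.0)
    half = max(1, int(np.ceil(truncate_sigmas * sigma_t * sfreq)))
    t = np.arange(-half, half + 1) / sfreq
    psi = np.exp(-((t / a) ** 2) / bandwidth) * np.exp(2j * np.pi * center_freq * t / a)
    psi /= np.sum(np.abs(psi))
    return 2.0 * psi  # analytic-signal doubling: unit cosine -> |W| ~ 1


def morlet_cwt(ep: EpochedEEG, grid: FrequencyGrid, bandwidth: float = 1.0,
               center_freq: float = 1.0, dtype=np.complex128) -> TFDecomposition:
    """Morlet CWT of every trial and channel at the grid frequencies.

    Convolution is FFT-based with zero padding; an edge mask flags samples
    within one envelope e-folding width of the epoch borders (cone of
    influence).
    """
    nyq = ep.sfreq / 2.0
    if grid.freqs[-1] >= nyq:
        raise ValueError("grid contains frequencies at or above Nyquist")
    n = ep.n_samples
    flat = ep.data.reshape(-1, n)
    out = np.empty((flat.shape[0], grid.n_freqs, n), dtype=dtype)
    edge = np.zeros((grid.n_freqs, n), dtype=bool)
    for fi, f in enumerate(grid.freqs):
        ker = morlet_kernel(f, ep.sfreq, bandwidth, center_freq)
        klen = ker.size
        nfft = next_fast_len(n + klen - 1)
        spec = fft(flat, nfft, axis=-1) * fft(ker, nfft)
        conv = ifft(spec, axis=-1)
        start = (klen - 1) // 2
        out[:, fi, :] = conv[:, start:start + n]
        efold = int(np.ceil((center_freq / f) * np.sqrt(bandwidth) * ep.sfreq))
        if efold >= n:
            warnings.warn(
                f"epoch shorter than the wavelet e-folding support at {f:.3g} Hz; "
                "all samples flagged as edge-contaminated")
            edge[fi, :] = True
        else:
            edge[fi, :efold] = True
            if efold > 0:
                edge[fi, -efold:] = True
    coeffs = out.reshape(ep.n_trials, ep.n_channels, grid.n_freqs, n)
    return TFDecomposition(coeffs=coeffs, grid=grid, times=ep.times.copy(), sfreq=ep.sfreq,
                           ch_names=list(ep.ch_names), bandwidth=bandwidth,
                           center_freq=center_freq, edge_mask=edge)
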