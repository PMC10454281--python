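"""Epoched EEG container shared by all analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def window_to_sample_bounds(window_ms: tuple[float, float], sfreq: float) -> tuple[int, int]:
    """Convert an (start, end) ms window to half-open sample-index bounds.

    Fractional bounds are truncated toward zero (a 300 ms window at 256 Hz is
    76.8 samples wide and covers the 76 on-grid samples [-38, 38)).
    """
    start, end = window_ms
    if end <= start:
        raise ValueError("window end must exceed window start")
    i0 = int(np.trunc(np.round(start * sfreq / 1000.0, 9)))
    i1 = int(np.trunc(np.round(end * sfreq / 1000.0, 9)))
    return i0, i1


@dataclass
class EpochedEEG:
    """Response-locked epochs: trials x channels x samples.

    ``times`` is in milliseconds relative to the locking event (button press),
    strictly increasing with uniform step 1000/sfreq, and must contain 0 ms on
    the sample grid.  ``data`` is in microvolts, or in CSD units (uV/m^2 on the
    unit sphere) after the surface Laplacian, indicated by ``is_csd``.
    """

    data: np.ndarray
    sfreq: float
    times: np.ndarray
    ch_names: list[str]
    metadata: pd.DataFrame | None = None
    is_csd: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if self.data.shape[1] != len(self.ch_names):
            raise ValueError("channel count mismatch between data and ch_names")
        if self.data.shape[2] != self.times.size:
            raise ValueError("sample count mismatch between data and times")
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")
        step = 1000.0 / self.sfreq
        dt = np.diff(self.times)
        if self.times.size > 1 and not np.allclose(dt, step, rtol=0, atol=1e-6 * step):
            raise ValueError("time axis must be uniform with step 1000/sfreq ms")
        if not (self.times[0] <= 0.0 <= self.times[-1]):
            raise ValueError("0 ms (the locking event) must lie inside the epoch")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch data contains non-finite values")
        if self.metadata is not None and len(self.metadata) != self.data.shape[0]:
            raise ValueError("metadata row count must equal the number of trials")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def time_mask(self, window_ms: tuple[float, float]) -> np.ndarray:
        """Boolean sample mask for the half-open window [start, end) in ms.

        The window bounds are converted to sample indices by truncation toward
        zero, and the index interval is half-open, so a 300 ms window at
        256 Hz covers exactly 76 on-grid samples.
        """
        i0, i1 = window_to_sample_bounds(window_ms, self.sfreq)
        k = np.round(self.times * self.sfreq / 1000.0).astype(int)
        return (k >= i0) & (k < i1)

    def copy_with(self, **kwargs) -> "EpochedEEG":
        fields = dict(
            data=self.data,
            sfreq=self.sfreq,
            times=self.times,
            ch_names=list(self.ch_names),
            metadata=None if self.metadata is None else self.metadata.copy(),
            is_csd=self.is_csd,
        )
        fields.update(kwargs)
        return EpochedEEG(**fields)
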