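import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from eegmotor.layout import default_biosemi128


@pytest.fixture(scope="session")
def layout128():
    return default_biosemi128()


@pytest.fixture(scope="session")
def layout16(layout128):
    """Evenly spaced 16-channel subset of the reference montage."""
    idx = np.linspace(0, 127, 16).round().astype(int)
    return layout128.subset([layout128.labels[i] for i in idx])


def make_epochs(data, sfreq=256.0, t0_index=None, ch_names=None):
    """EpochedEEG from a raw array with 0 ms placed at ``t0_index``."""
    from eegmotor.epochs import EpochedEEG

    data = np.asarray(data, dtype=float)
    n = data.shape[-1]
    if t0_index is None:
        t0_index = n // 2
    times = (np.arange(n) - t0_index) / sfreq * 1000.0
    if ch_names is None:
        ch_names = [f"ch{i}" for i in range(data.shape[1])]
    return EpochedEEG(data=data, sfreq=sfreq, times=times, ch_names=ch_names)
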