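"""Synthetic two-group EEG cohorts with known ground truth.

Each subject is simulated as response-locked epochs containing:

* spatially mixed 1/f^gamma background noise (a random orthogonal mixing
  matrix creates zero-lag inter-channel correlation of the kind volume
  conduction produces — exactly what dwPLI should reject),
* an event-locked oscillatory burst at a delta-theta frequency whose
  per-trial phase is von Mises distributed with group-specific concentration
  kappa (ground-truth ITC = I1(kappa)/I0(kappa)),
* an induced oscillation with uniform random phase per trial whose amplitude
  is multiplied by a group-specific gain g inside the event window
  (ground-truth ERSP = 20*log10(g) dB), and
* lagged common signals injected into coupled channel pairs (nonzero-lag
  coupling that dwPLI detects).

Defaults emulate a typical high-density visually-cued finger-tapping cohort
(128 channels, 256 Hz epochs over [-4500, 2500) ms, 113 trials per young
subject and 88 per old subject and hand, 22 subjects per group), with the old
group given higher phase concentration, a stronger event-related
desynchronization, and stronger coupling — the direction of group effects the
pipeline is expected to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ive

from .epochs import EpochedEEG, window_to_sample_bounds

BIOSEMI128_LABELS = [f"{bank}{i}" for bank in "ABCD" for i in range(1, 33)]


@dataclass
class GroupParams:
    """Per-group generative parameters."""

    n_trials: int
    kappa: float              # von Mises concentration of the locked burst phase
    induced_gain: float       # amplitude gain g inside the event window
    coupling_amplitude: float

    def __post_init__(self) -> None:
        if self.n_trials < 2:
            raise ValueError("need at least 2 trials")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.induced_gain <= 0:
            raise ValueError("induced gain must be positive")
        if self.coupling_amplitude < 0:
            raise ValueError("coupling amplitude must be >= 0")


@dataclass
class SyntheticCohortConfig:
    n_subjects: int = 22
    sfreq: float = 256.0
    window_ms: tuple = (-4500.0, 2500.0)
    ch_names: list[str] = field(default_factory=lambda: list(BIOSEMI128_LABELS))
    noise_exponent: float = 1.0     # 1/f^gamma background
    noise_amplitude: float = 10.0   # uV rms
    pl_freq: float = 3.0            # Hz, phase-locked burst
    pl_amplitude: float = 20.0
    pl_sigma_ms: float = 150.0      # Gaussian envelope sigma, centred at 0 ms
    pl_target_channels: list[str] = field(
        default_factory=lambda: ["A5", "A6", "A7", "A16", "A17", "A18", "D27", "D28"])
    induced_freq: float = 11.0      # Hz, alpha-band induced oscillation
    induced_base_amplitude: float = 10.0
    induced_window_ms: tuple = (-150.0, 150.0)
    induced_target_channels: list[str] = field(
        default_factory=lambda: ["B20", "B21", "B22", "D18", "D19", "D20"])
    coupling_freqs: tuple = (3.0, 5.0)  # Hz, delta- and theta-band lagged coupling
    coupling_phase_lag: float = np.pi / 2
    # coupled channels are kept disjoint from the phase-locked targets so the
    # random-phase coupling signal does not dilute ITC at (pl_freq, 0)
    coupling_pairs: list = field(
        default_factory=lambda: [("A9", "D24"), ("A10", "D23")])
    groups: dict = field(default_factory=lambda: {
        "young": GroupParams(n_trials=113, kappa=1.0, induced_gain=0.8, coupling_amplitude=6.0),
        "old": GroupParams(n_trials=88, kappa=4.0, induced_gain=0.5, coupling_amplitude=12.0),
    })
    equalize_trials: bool = False   # subsample both groups to the common minimum

    def __post_init__(self) -> None:
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("duplicate channel names")
        if not (0 < self.coupling_phase_lag < np.pi):
            raise ValueError("coupling phase lag must lie in (0, pi)")
        for chans in (self.pl_target_channels, self.induced_target_channels):
            missing = set(chans) - set(self.ch_names)
            if missing:
                raise ValueError(f"target channels not in layout: {sorted(missing)}")
        for a, b in self.coupling_pairs:
            if a not in self.ch_names or b not in self.ch_names:
                raise ValueError(f"coupling pair ({a}, {b}) not in channel set")
        if self.pl_amplitude > 0 and not self.pl_target_channels:
            raise ValueError("phase-locked amplitude is nonzero but target channel set is empty")
        i0, i1 = window_to_sample_bounds(self.window_ms, self.sfreq)
        w0, w1 = window_to_sample_bounds(self.induced_window_ms, self.sfreq)
        if w0 < i0 or w1 > i1:
            raise ValueError("induced event window lies outside the epoch")

    @classmethod
    def desk_scale(cls, n_subjects: int = 12, n_channels: int = 24,
                   n_trials: int = 40) -> "SyntheticCohortConfig":
        """A reduced cohort for desk-scale runs: fewer subjects, a spatial
        subsample of the 128-channel montage and fewer trials, with the same
        effect parameters as the full configuration."""
        idx = np.unique(np.linspace(0, 127, n_channels).round().astype(int))
        chans = [BIOSEMI128_LABELS[i] for i in idx]
        q = len(chans)
        if q < 8:
            raise ValueError("desk-scale configuration needs at least 8 channels")
        # disjoint channel roles: phase-locked targets, induced targets,
        # coupled pairs (coupling must not contaminate ITC ground truth)
        pl = [chans[i] for i in (2, 3, q - 3, q - 2)]
        ind = [chans[1], chans[q // 2]]
        used = set(pl) | set(ind)
        free = [i for i in range(q) if chans[i] not in used]
        pairs = [(chans[free[k]], chans[free[-1 - k]])
                 for k in range(min(2, len(free) // 2))]
        cfg = cls(n_subjects=n_subjects, ch_names=chans, pl_target_channels=pl,
                  induced_target_channels=ind, coupling_pairs=pairs)
        cfg.groups = {name: replace(p, n_trials=n_trials) for name, p in cfg.groups.items()}
        return cfg

    @classmethod
    def from_dict(cls, payload: dict) -> "SyntheticCohortConfig":
        payload = dict(payload)
        if "groups" in payload:
            payload["groups"] = {name: GroupParams(**gp)
                                 for name, gp in payload["groups"].items()}
        if "coupling_pairs" in payload:
            payload["coupling_pairs"] = [tuple(p) for p in payload["coupling_pairs"]]
        for key in ("window_ms", "induced_window_ms", "coupling_freqs"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticCohortConfig":
        """Load a cohort configuration from a YAML mapping."""
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class GroundTruth:
    """Theoretical values the estimators should recover."""

    itc: dict                # group -> I1(kappa)/I0(kappa) at (pl_freq, 0 ms)
    ersp_db: dict            # group -> 20*log10(g) in the induced band/window
    pl_freq: float
    induced_freq: float
    target_channels: list[str]
    induced_channels: list[str]
    coupled_pairs: list
    coupling_freqs: tuple
    coupling_phase_lag: float


def theoretical_itc(kappa: float) -> float:
    """Population resultant length of a von Mises distribution, I1(k)/I0(k)."""
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if np.isinf(kappa):
        return 1.0
    # exponentially scaled Bessel ratio is stable for large kappa
    return float(ive(1, kappa) / ive(0, kappa))


def _one_over_f_noise(rng: np.random.Generator, shape: tuple, n_samples: int,
                      exponent: float, sfreq: float) -> np.ndarray:
    white = rng.standard_normal(shape + (n_samples,))
    freqs = np.fft.rfftfreq(n_samples, 1.0 / sfreq)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = np.fft.rfft(white, axis=-1) * gain
    noise = np.fft.irfft(spec, n=n_samples, axis=-1)
    return noise / noise.std()


def generate_subject(config: SyntheticCohortConfig, group: str, seed,
                     subject_id: str | None = None) -> EpochedEEG:
    """One subject's epochs; bitwise deterministic given (config, group, seed)."""
    if group not in config.groups:
        raise KeyError(f"unknown group {group!r}")
    gp = config.groups[group]
    rng = np.random.default_rng(seed)
    i0, i1 = window_to_sample_bounds(config.window_ms, config.sfreq)
    nt = i1 - i0
    times = (i0 + np.arange(nt)) / config.sfreq * 1000.0
    t = times / 1000.0
    nc = len(config.ch_names)
    k = gp.n_trials

    # spatially mixed 1/f background
    noise = _one_over_f_noise(rng, (k, nc), nt, config.noise_exponent, config.sfreq)
    Q, _ = np.linalg.qr(rng.standard_normal((nc, nc)))
    data = config.noise_amplitude * np.einsum("ij,kjt->kit", Q, noise)

    # event-locked burst with von Mises phase
    if config.pl_amplitude > 0:
        env = np.exp(-(t**2) / (2 * (config.pl_sigma_ms / 1000.0) ** 2))
        theta = rng.vonmises(0.0, gp.kappa, size=k)
        burst = config.pl_amplitude * env * np.cos(
            2 * np.pi * config.pl_freq * t[None, :] + theta[:, None])
        idx = [config.ch_names.index(c) for c in config.pl_target_channels]
        data[:, idx, :] += burst[:, None, :]

    # induced oscillation: uniform phase, amplitude gain g inside the window
    if config.induced_base_amplitude > 0:
        w0, w1 = window_to_sample_bounds(config.induced_window_ms, config.sfreq)
        kidx = np.round(times * config.sfreq / 1000.0).astype(int)
        in_win = (kidx >= w0) & (kidx < w1)
        amp = config.induced_base_amplitude * np.where(in_win, gp.induced_gain, 1.0)
        phi = rng.uniform(0, 2 * np.pi, size=k)
        osc = amp[None, :] * np.cos(2 * np.pi * config.induced_freq * t[None, :] + phi[:, None])
        idx = [config.ch_names.index(c) for c in config.induced_target_channels]
        data[:, idx, :] += osc[:, None, :]

    # lagged common signals in coupled pairs, one per coupling frequency
    if gp.coupling_amplitude > 0:
        for f_c in config.coupling_freqs:
            for a, b in config.coupling_pairs:
                ia, ib = config.ch_names.index(a), config.ch_names.index(b)
                phi = rng.uniform(0, 2 * np.pi, size=k)
                base = 2 * np.pi * f_c * t[None, :] + phi[:, None]
                data[:, ia, :] += gp.coupling_amplitude * np.cos(base)
                data[:, ib, :] += gp.coupling_amplitude * np.cos(base - config.coupling_phase_lag)

    meta = pd.DataFrame({
        "trial": np.arange(k),
        "subject": subject_id or f"{group}-{seed}",
        "group": group,
        "hand": "right",
    })
    return EpochedEEG(data=data, sfreq=config.sfreq, times=times,
                      ch_names=list(config.ch_names), metadata=meta)


@dataclass
class CohortData:
    groups: dict          # group -> list[EpochedEEG]
    ground_truth: GroundTruth
    subject_seeds: dict


def generate_cohort(config: SyntheticCohortConfig, master_seed: int = 0) -> CohortData:
    """Two groups of subjects with per-subject seeds derived from the master seed."""
    if config.n_subjects < 2:
        raise ValueError("need at least 2 subjects per group for group statistics")
    rng = np.random.default_rng(master_seed)
    group_names = list(config.groups)
    seeds = rng.integers(0, 2**31 - 1, size=(len(group_names), config.n_subjects))
    n_common = min(gp.n_trials for gp in config.groups.values())
    out, seed_map = {}, {}
    for gi, name in enumerate(group_names):
        subs = []
        for si in range(config.n_subjects):
            ep = generate_subject(config, name, int(seeds[gi, si]),
                                  subject_id=f"{name}{si:02d}")
            if config.equalize_trials and ep.n_trials > n_common:
                sub_rng = np.random.default_rng(int(seeds[gi, si]) + 1)
                keep = np.sort(sub_rng.choice(ep.n_trials, n_common, replace=False))
                ep = ep.copy_with(data=ep.data[keep],
                                  metadata=ep.metadata.iloc[keep].reset_index(drop=True))
            subs.append(ep)
        out[name] = subs
        seed_map[name] = seeds[gi].tolist()
    gt = GroundTruth(
        itc={name: theoretical_itc(gp.kappa) for name, gp in config.groups.items()},
        ersp_db={name: 20 * np.log10(gp.induced_gain) for name, gp in config.groups.items()},
        pl_freq=config.pl_freq,
        induced_freq=config.induced_freq,
        target_channels=list(config.pl_target_channels),
        induced_channels=list(config.induced_target_channels),
        coupled_pairs=list(config.coupling_pairs),
        coupling_freqs=tuple(config.coupling_freqs),
        coupling_phase_lag=config.coupling_phase_lag,
    )
    return CohortData(groups=out, ground_truth=gt, subject_seeds=seed_map)
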