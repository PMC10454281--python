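# eegmotor

Analysis toolkit for movement-related high-density EEG: how does the brain's
oscillatory activity around a voluntary button press differ between groups
(e.g. old vs. young adults)? The package implements the full sensor-space
chain used in comparative motor-execution studies —

* **CSD**: spherical-spline surface Laplacian (Perrin kernels, m = 4,
  lambda = 1e-5, Legendre degree 10) to reduce volume conduction,
* **Time-frequency**: complex Morlet CWT ('cmor1-1') on a logarithmic grid
  (0.32–73 Hz, ratio 1.1),
* **ERSP**: single-trial gain model,
  `ERSP(f,t) = 10 log10( (1/n) Σ_k |F_k(f,t)|² / μ'_B(f,k) )` with per-trial
  baseline μ'_B from [-3500, -3000) ms,
* **ITC**: inter-trial coherence `|(1/n) Σ_k exp(i φ_k(f,t))|` ∈ [0, 1],
* **Connectivity**: debiased weighted phase lag index (dwPLI) per band in the
  300 ms window around the press, with weighted graph metrics (node strength,
  global and local efficiency, 2% proportional thresholding),
* **Statistics**: cluster-based permutation tests over channel × frequency ×
  time (cluster alpha 0.001, max-cluster-mass null, distance-0.4 +
  triangulation spatial adjacency) and permutation tests on graph metrics,

plus a **synthetic two-group cohort generator** whose ground truth
(von Mises phase concentration → ITC = I1(κ)/I0(κ); event amplitude gain g →
ERSP = 20 log10 g dB; lagged coupled pairs → dwPLI) makes every stage
verifiable by parameter recovery. See `docs/methods.md` for the model
details.

## Worked example

```python
import numpy as np
from eegmotor import (SyntheticCohortConfig, generate_subject, theoretical_itc,
                      make_frequency_grid, morlet_cwt, itc)

cfg = SyntheticCohortConfig.desk_scale(n_channels=8, n_trials=100)
cfg.groups["old"].kappa = 2.0          # phase concentration of the 3 Hz burst
ep = generate_subject(cfg, "old", seed=42)

grid = make_frequency_grid(cfg.pl_freq / 1.1**2, cfg.pl_freq * 1.1**2.5, 1.1)
m = itc(morlet_cwt(ep, grid))
fi = np.argmin(abs(grid.freqs - cfg.pl_freq))
ti = np.argmin(abs(ep.times))
ch = ep.ch_names.index(cfg.pl_target_channels[0])
print(f"estimated ITC {m.values[ch, fi, ti]:.3f}  theory {theoretical_itc(2.0):.3f}")
```

prints

```
estimated ITC 0.626  theory 0.698
```

— the estimated inter-trial coherence at the burst frequency and the button
press tracks the population resultant length of the von Mises phase
distribution (one 100-trial subject at the default background-noise level;
at low noise the 50-seed mean recovers the theoretical value within 3
standard errors, see `tests/test_acceptance.py`).

The numbered drivers under `analysis/` run the narrative study on a
synthetic cohort: `01_simulate_cohort.py` (two groups with planted effects),
`02_ersp_itc_maps.py` (band/window ERSP and ITC summaries),
`03_connectivity_graphs.py` (dwPLI graphs and metrics),
`04_group_statistics.py` (cluster and permutation statistics; on the default
seed it reports a significant between-group delta–theta ITC cluster over the
planted channels and higher old-group global efficiency in delta and theta).
Tables land in `results/`. A thin CLI mirrors the same steps
(`eegmotor simulate|preprocess|csd|run|report`).

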