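# Methods

`eegmotor` implements the analysis chain used to compare movement-related
brain activity between groups from high-density EEG: spatial sharpening with
the surface Laplacian, single-trial time-frequency decomposition, two
complementary oscillatory statistics (ERSP and ITC), phase-lag-based
functional connectivity with weighted graph metrics, and nonparametric
cluster statistics. A synthetic cohort generator with known ground truth
closes the loop: every estimator is validated by parameter recovery.

## Data model

All stages consume response-locked epochs (`EpochedEEG`): trials x channels x
samples in microvolts at 256 Hz, with a millisecond time axis whose 0 ms lies
on the sample grid at the button press. The reference montage is the
128-channel Biosemi ABC layout (A1..D32); electrode positions are normalized
to the unit sphere. Millisecond windows are converted to sample indices by
truncation toward zero and applied half-open, so the 300 ms analysis window
at 256 Hz covers exactly 76 samples and the 500 ms baseline window 128.

## Preprocessing

Continuous recordings (BDF/EDF, read through MNE) are band-limited with
cascaded 4th-order Butterworth high- and low-pass filters at 0.5 and 70 Hz
plus a 50 Hz notch (Q = 45), all applied forward-backward (zero phase, squared
magnitude response). Epochs of [-4500, 2500) ms are cut around trigger
events; polyphase resampling takes 2048 Hz recordings to 256 Hz. Bad channels
are replaced by spherical-spline interpolants fitted on the remaining
channels. Independent-component artifact removal is deliberately out of
scope; callers supply the bad-channel mask.

## Surface Laplacian (CSD)

Scalp potentials are converted to current source density with Perrin-style
spherical splines. The interpolation and Laplacian kernels are truncated
Legendre series

    g(x) = (1/4pi) sum_{n=1..N} (2n+1)/(n(n+1))^m P_n(x),
    h(x) = (1/4pi) sum_{n=1..N} (2n+1)/(n(n+1))^(m-1) P_n(x),

evaluated by Clenshaw recurrence. Defaults: flexibility m = 4, smoothing
lambda = 1e-5, N = 10, unit sphere radius. N is configurable because many
implementations use larger truncation orders; at the 128-channel density the
resulting CSD patterns are nearly identical (the focal-source surround
annulus is stable for N = 10..50). The spline system is solved once per
layout and the composite CSD transform applied as a single matrix per sample.
Absolute CSD scale (uV/m^2 up to the head-radius factor) does not affect any
downstream statistic.

## Time-frequency decomposition

Complex Morlet CWT with the analytic mother wavelet
psi(t) = (pi B)^(-1/2) exp(-t^2/B) exp(i 2 pi C t), B = C = 1 ('cmor1-1'),
dilated by a = C/f per target frequency. The frequency grid is geometric,
f_k = 0.32 * 1.1^k Hz up to 73 Hz (57 frequencies, anchored ascending from
fmin; the anchor is configurable because only the ratio is canonical).
Kernels are L1-normalized and doubled, so a unit-amplitude in-band sinusoid
yields |F| ~ 1 and arg F equals its instantaneous cosine phase — both
properties are unit-tested against analytic signals. Convolution is
FFT-based with zero padding; a cone-of-influence mask flags samples within
one envelope e-folding of the epoch borders. With [-4500, 2500) ms epochs the
-150..150 ms statistics window is uncontaminated for all grid frequencies
above ~0.5 Hz.

## ERSP and ITC

ERSP uses the single-trial gain model: each trial's power is divided by that
trial's own mean baseline power (baseline [-3500, -3000) ms, chosen ahead of
the motor preparation period), then

    ERSP(f,t) = 10 log10( (1/n) sum_k |F_k(f,t)|^2 / mu'_B(f,k) )  [dB].

The per-trial normalization makes ERSP exactly invariant to global amplitude
rescaling; cells with exactly zero baseline power (possible only for
degenerate synthetic input) are excluded from the trial mean rather than
producing infinities. ITC is the resultant length of the across-trial unit
phase vectors, in [0, 1]. Band summaries average over the half-open band
intervals (delta 1-4, theta 4-8, alpha 8-15, beta 15-30, gamma 30-70 Hz) and
the event window; half-open edges prevent double counting at the shared band
boundaries.

## Functional connectivity and graph metrics

The debiased weighted phase lag index is computed per (frequency, time) cell
from the imaginary part of the trial cross-spectrum and averaged over the
band x window cells (the pooled-cross-spectrum alternative is available).
dwPLI ignores zero-lag coupling, which is exactly the signature of volume
conduction — the generator's spatially mixed noise exercises this. The
debiased estimator can be negative at finite trial counts; matrices destined
for graph analysis are clamped at zero after band averaging (signed matrices
remain available). Graph metrics follow the weighted Brain Connectivity
Toolbox conventions with connection lengths 1/w: node strength (row sums),
global efficiency (mean inverse shortest-path length; unreachable pairs
contribute zero), and local efficiency (neighbourhood subgraph efficiency on
cube-root-transformed lengths, zero for degree < 2). Proportional
thresholding keeps the strongest fraction of edges (round-half-up count,
deterministic index-based tie-break). All three metrics are verified against
brute-force path-enumeration oracles on random small graphs.

## Cluster statistics

Within-group (vs. baseline, paired t) and between-group (pooled-variance
two-sample t) maps over channel x frequency x time (-150..150 ms, 0.5-70 Hz)
are thresholded two-sided at cluster-forming alpha 0.001; supra-threshold
cells of equal sign are clustered through time (+-1 sample), frequency (+-1
grid step on the logarithmic grid) and space. Spatial adjacency is the union
of electrode pairs closer than 0.4 (Euclidean on the unit sphere) and the
Delaunay triangulation edges of the azimuthal-equidistant projection — union
rather than intersection, configurable. Cluster mass (summed t) is referred
to the permutation null of the maximum absolute cluster mass (sign flips for
the paired test, group relabellings for the independent test), with
p = (1 + #{null >= observed}) / (n_perm + 1), so p is never zero and the test
is valid at finite permutation counts. Scalar graph metrics are compared with
a two-sided permutation test on the absolute group-mean difference (exact
enumeration available for small groups); per-band tests are reported without
cross-band correction, with a Bonferroni option left to the caller.

## Synthetic cohorts and ground truth

Each synthetic subject combines: (1) 1/f^gamma background noise (gamma = 1)
mixed through a random orthogonal channel matrix — realistic zero-lag
inter-channel correlation that dwPLI must reject; (2) a movement-locked
3 Hz burst (Gaussian envelope, sigma 150 ms, centred at the button press)
whose per-trial phase is von Mises with group concentration kappa, so the
population ITC at the burst frequency is the Bessel ratio I1(kappa)/I0(kappa);
(3) an 11 Hz induced oscillation with uniform random phase whose amplitude is
multiplied by gain g inside the event window, so the band ERSP is
20 log10(g) dB; and (4) lagged (pi/2) common oscillations at 3 and 5 Hz
injected into coupled channel pairs. The channel roles (ITC targets, ERSP
targets, coupled pairs) are disjoint, so each ground-truth value is
uncontaminated by the other components.

The default configuration matches a typical high-density study: 22 subjects
per group, 128 channels, 256 Hz epochs over [-4500, 2500) ms, 113 trials per
young and 88 per old subject; the old group has higher kappa (4 vs 1),
stronger desynchronization (g = 0.5 vs 0.8) and stronger coupling (12 vs 6).
Because ITC is upward-biased at small trial counts, optional trial-count
equalization (seeded subsampling to the common minimum) is provided and off
by default. The generator does not model biophysical volume conduction,
artifacts (blinks, EMG) or inter-subject anatomical variability, so passing
recovery tests demonstrate estimator correctness under the generative model,
not robustness to real-world artifacts.

## Problem sizes used by the validation suite

The test suite and analysis scripts use deliberately reduced sizes chosen as
the smallest cohorts at which every planted effect is still clearly
recoverable: end-to-end group analysis with 12 subjects per group, a
24-channel spatial subsample of the montage, 40 trials per subject and 500
permutations; parameter-recovery runs with 8 channels, 100 trials and 50
seeds on frequency grids bracketing the component frequency; cluster-test
calibration on 16 channels x 10 frequencies x 20 samples with 12 subjects,
500 permutations and 200 replicate runs. The full-scale defaults (22
subjects, 128 channels, 10,000 permutations) remain the configuration
defaults throughout the library.

## Numerical choices and edge cases

* Zero-phase filtering bottoms out at ~1e-8..1e-7 impulse-response asymmetry
  in double precision; the zero-lag property is additionally checked by
  cross-correlation.
* dwPLI cells whose denominator vanishes (all imaginary cross-spectra zero)
  are defined as 0, consistent with insensitivity to zero-phase coupling.
* Degenerate t-statistics (zero variance cells) are mapped to 0 rather than
  +-inf before clustering.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; cohort generation derives per-subject seeds
  from the master seed, and rerunning any pipeline stage with the same
  configuration reproduces outputs byte-for-byte.

## Known limitations

* Sensor space only; no source localization or realistic head geometry.
* No ICA-based artifact pipeline (a bad-channel interpolation hook exists).
* The independent cluster test assumes exchangeability under the null;
  strongly unequal group variances are not specially handled.
* Local efficiency follows one (the current toolbox) weighted definition;
  older variants differ in how the cube root enters the neighbourhood paths.
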